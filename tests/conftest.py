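import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ranktraits as rt

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def random_pedigree(rng: np.random.Generator, n: int, p_founder: float = 0.35) -> rt.PedigreeTable:
    """Random valid pedigree: parents drawn among earlier individuals."""
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    for i in range(1, n):
        if rng.random() > p_founder:
            sire[i] = rng.integers(1, i + 1)
        if rng.random() > p_founder:
            dam[i] = rng.integers(1, i + 1)
    return rt.PedigreeTable(sire=sire, dam=dam)


def founders_pedigree(n: int) -> rt.PedigreeTable:
    return rt.PedigreeTable(sire=np.zeros(n, dtype=np.int64), dam=np.zeros(n, dtype=np.int64))


def make_chain(model, data, pedigree, seed=0, **kw) -> rt.GibbsChain:
    return rt.GibbsChain(
        model, data, rt.build_a_inverse(pedigree), rng=np.random.default_rng(seed), **kw
    )


@pytest.fixture(scope="session")
def tiny_study() -> rt.SimStudy:
    """Small but non-degenerate simulated competition study."""
    cfg = rt.SimConfig(
        n_sires=5, n_dams=20, n_offspring=80, n_events=40, event_size=6, seed=7
    )
    return rt.simulate_study(cfg)
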