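"""Synthetic competition data with known genetic truth.

The generator emulates a one-generation horse-breeding study: unrelated
sires and dams produce offspring that compete in randomly drawn events of
fixed size.  Each start yields a finishing position — the descending order
of latent liabilities ``l = a_l + e_l`` within the event — and a correlated
continuous record ``y = a_y + e_y``, with the residual pair drawn jointly so
the within-row residual correlation is well defined.

Default settings are the validation design used throughout this package:
100 sires x 500 dams -> 2000 horses, 2000 events of 10 (10 starts per horse
on average), liability variances 0.25 / 1 (h² = 0.2), continuous-trait
variances 1 / 2 (h² = 1/3), genetic correlation 0.3 and residual
correlation -0.2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import io as _io
from .model import (
    ADDITIVE,
    RANKING,
    SYSTEMATIC,
    ConfigurationError,
    DataTable,
    EffectSpec,
    EventTable,
    McmcConfig,
    ModelSpec,
    TraitSpec,
    build_event_table,
)
from .pedigree import PedigreeTable


@dataclass(frozen=True)
class SimConfig:
    """Study design and true parameters of the simulation."""

    n_sires: int = 100
    n_dams: int = 500
    n_offspring: int = 2000
    n_events: int = 2000
    event_size: int = 10
    sigma2_a_l: float = 0.25
    sigma2_e_l: float = 1.0
    sigma2_a_y: float = 1.0
    sigma2_e_y: float = 2.0
    r_g: float = 0.3
    r_e: float = -0.2
    seed: int = 0

    def __post_init__(self):
        for f in ("sigma2_a_l", "sigma2_e_l", "sigma2_a_y", "sigma2_e_y"):
            if getattr(self, f) <= 0:
                raise ConfigurationError(f"{f} must be > 0")
        for f in ("r_g", "r_e"):
            if not -1 < getattr(self, f) < 1:
                raise ConfigurationError(f"{f} must lie in (-1, 1)")
        if self.event_size > self.n_offspring:
            raise ConfigurationError("event_size cannot exceed n_offspring")

    @property
    def n_founders(self) -> int:
        return self.n_sires + self.n_dams

    @property
    def n_individuals(self) -> int:
        return self.n_founders + self.n_offspring

    @property
    def mean_starts(self) -> float:
        return self.n_events * self.event_size / self.n_offspring

    @property
    def g_true(self) -> np.ndarray:
        cov = self.r_g * np.sqrt(self.sigma2_a_l * self.sigma2_a_y)
        return np.array([[self.sigma2_a_l, cov], [cov, self.sigma2_a_y]])

    @property
    def r_true(self) -> np.ndarray:
        cov = self.r_e * np.sqrt(self.sigma2_e_l * self.sigma2_e_y)
        return np.array([[self.sigma2_e_l, cov], [cov, self.sigma2_e_y]])

    @property
    def h2_liability(self) -> float:
        return self.sigma2_a_l / (self.sigma2_a_l + self.sigma2_e_l)

    @property
    def h2_continuous(self) -> float:
        return self.sigma2_a_y / (self.sigma2_a_y + self.sigma2_e_y)


def paper_config(**overrides) -> SimConfig:
    """The full-size validation design."""
    return SimConfig(**overrides)


def scaled_config(**overrides) -> SimConfig:
    """A 40%-scale replicate keeping 10 starts per horse."""
    base = dict(n_sires=40, n_dams=200, n_offspring=800, n_events=800)
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class TruthTable:
    """True quantities stored beside the generated files, never read by the sampler."""

    breeding_values: np.ndarray       # (N, 2): liability, continuous
    event_mean_additive: np.ndarray   # (K,) mean true a_l of each event's starters
    start_liabilities: np.ndarray     # (n_rows,) realized liability of each start
    config: SimConfig

    @property
    def true_parameters(self) -> dict[str, float]:
        c = self.config
        return {
            "G[1,1]": c.sigma2_a_l, "G[2,2]": c.sigma2_a_y,
            "R[1,1]": c.sigma2_e_l, "R[2,2]": c.sigma2_e_y,
            "h2_liability": c.h2_liability, "h2_performance": c.h2_continuous,
            "r_g_liability_performance": c.r_g,
            "r_e_liability_performance": c.r_e,
        }


def simulate_pedigree(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[PedigreeTable, np.ndarray]:
    """Founders plus offspring with true bivariate breeding values.

    Founders draw their breeding values from MVN(0, G); each offspring gets a
    uniformly random sire and dam and adds a Mendelian-sampling deviation
    MVN(0, G/2) to the parental mean (founder parents, no inbreeding).
    """
    s, d, o = cfg.n_sires, cfg.n_dams, cfg.n_offspring
    n = cfg.n_individuals
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    sire[s + d:] = rng.integers(1, s + 1, size=o)
    dam[s + d:] = s + rng.integers(1, d + 1, size=o)
    low = np.linalg.cholesky(cfg.g_true)
    bv = np.empty((n, 2))
    bv[: s + d] = rng.standard_normal((s + d, 2)) @ low.T
    mend = rng.standard_normal((o, 2)) @ (low.T / np.sqrt(2.0))
    bv[s + d:] = 0.5 * (bv[sire[s + d:] - 1] + bv[dam[s + d:] - 1]) + mend
    return PedigreeTable(sire=sire, dam=dam), bv


def simulate_events(
    cfg: SimConfig,
    ped: PedigreeTable,
    bv: np.ndarray,
    rng: np.random.Generator,
) -> tuple[DataTable, EventTable, TruthTable]:
    """Random events, ranks from liability order, paired continuous records."""
    k, m = cfg.n_events, cfg.event_size
    first = cfg.n_founders  # 0-based index of the first offspring
    horses = np.empty((k, m), dtype=np.int64)
    for e in range(k):
        horses[e] = first + rng.choice(cfg.n_offspring, size=m, replace=False)
    flat = horses.ravel()
    resid = rng.standard_normal((k * m, 2)) @ np.linalg.cholesky(cfg.r_true).T
    liab = bv[flat, 0] + resid[:, 0]
    y = bv[flat, 1] + resid[:, 1]
    # finishing position: descending liability within the event
    order = np.argsort(-liab.reshape(k, m), axis=1)
    pos = np.empty((k, m), dtype=np.int64)
    rows = np.arange(k)[:, None]
    pos[rows, order] = np.arange(1, m + 1)

    n_rows = k * m
    levels = np.empty((n_rows, 3), dtype=np.int64)
    levels[:, 0] = 1                                       # general mean
    levels[:, 1] = np.repeat(np.arange(1, k + 1), m)       # event effect
    levels[:, 2] = flat + 1                                # animal
    values = np.full((n_rows, 2), np.nan)
    values[:, 1] = y
    event_ids = np.zeros((n_rows, 2), dtype=np.int64)
    positions = np.zeros((n_rows, 2), dtype=np.int64)
    event_ids[:, 0] = levels[:, 1]
    positions[:, 0] = pos.ravel()
    data = DataTable(
        levels=levels, values=values, event_ids=event_ids, positions=positions
    )
    truth = TruthTable(
        breeding_values=bv,
        event_mean_additive=bv[horses, 0].mean(axis=1),
        start_liabilities=liab,
        config=cfg,
    )
    model = study_model(cfg)
    return data, build_event_table(data, model), truth


def study_model(cfg: SimConfig) -> ModelSpec:
    """The analysis model of the validation study: mean + event + additive.

    The general mean applies to the continuous trait only: on the liability
    scale a mean is confounded with the event effects (every ranked row has
    exactly one event level), and the event effect is the liability's
    systematic location under winner-zeroing.
    """
    return ModelSpec(
        traits=[
            TraitSpec(name="liability", kind=RANKING, residual_variance=cfg.sigma2_e_l),
            TraitSpec(name="performance", kind="continuous"),
        ],
        effects=[
            EffectSpec(name="mean", kind=SYSTEMATIC, n_levels=1, traits=(1,)),
            EffectSpec(
                name="event", kind=SYSTEMATIC, n_levels=cfg.n_events,
                traits=(0,), is_event_effect=True,
            ),
            EffectSpec(
                name="animal", kind=ADDITIVE, n_levels=cfg.n_individuals,
                traits=(0, 1),
            ),
        ],
    )


@dataclass
class SimStudy:
    """One simulated dataset bundled with its analysis model and truth."""

    config: SimConfig
    model: ModelSpec
    pedigree: PedigreeTable
    data: DataTable
    events: EventTable
    truth: TruthTable


def simulate_study(cfg: SimConfig | None = None, seed: int | None = None) -> SimStudy:
    """Generate a complete study (pedigree, events, records, truth)."""
    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    ped, bv = simulate_pedigree(cfg, rng)
    data, events, truth = simulate_events(cfg, ped, bv, rng)
    return SimStudy(
        config=cfg, model=study_model(cfg), pedigree=ped,
        data=data, events=events, truth=truth,
    )


def write_simulation(
    out_dir: str | Path, study: SimStudy, mcmc: McmcConfig | None = None
) -> dict[str, Path]:
    """Write the three sampler input files plus the truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mcmc = mcmc or McmcConfig(
        n_iterations=100000, n_burnin=10000, thin=10, seed=study.config.seed
    )
    paths = {
        "parameters": out / "parameters.txt",
        "pedigree": out / "pedigree.txt",
        "data": out / "data.txt",
        "truth_bv": out / "truth_bv.txt",
        "truth_events": out / "truth_events.txt",
    }
    _io.write_parameters(
        paths["parameters"], study.model, mcmc, "data.txt", "pedigree.txt"
    )
    _io.write_pedigree(paths["pedigree"], study.pedigree)
    _io.write_data(paths["data"], study.data, study.model)
    bv = study.truth.breeding_values
    with open(paths["truth_bv"], "w") as fh:
        fh.write("individual\ttrue_bv_liability\ttrue_bv_performance\n")
        for i in range(bv.shape[0]):
            fh.write(f"{i + 1}\t{bv[i, 0]:.10g}\t{bv[i, 1]:.10g}\n")
    with open(paths["truth_events"], "w") as fh:
        fh.write("event\tmean_true_additive_liability\n")
        for e, v in enumerate(study.truth.event_mean_additive, start=1):
            fh.write(f"{e}\t{v:.10g}\n")
    return paths
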