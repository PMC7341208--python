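"""Plain-text input files: parameters, pedigree and data.

Parameter files are line-oriented ``KEY = value``; ``#`` starts a comment.
Recognised keys::

    DATAFILE, PEDIGREEFILE          paths (relative to the parameter file)
    NTRAITS                         number of traits
    TRAIT<i>_KIND                   continuous | threshold | ranking
    TRAIT<i>_NCAT                   categories (threshold traits only)
    EFFECT<j>_NAME                  label
    EFFECT<j>_CLASS                 systematic | random_environmental |
                                    additive_genetic
    EFFECT<j>_NLEVELS               number of levels
    EFFECT<j>_TRAITS                1-based trait indices (e.g. "1 2")
    EVENT_EFFECT                    1-based effect index or NONE
    NITER, NBURNIN, THIN, SEED      chain settings (THIN default 1, SEED 0)
    RANKING_RESIDUAL_VAR            fixed liability residual variance (1.0)
    G_PRIOR_DF / G_PRIOR_SCALE      optional proper inverted-Wishart priors;
    P_PRIOR_*, R_PRIOR_*            SCALE is the row-major matrix

The pedigree file holds whitespace-delimited ``individual sire dam`` triples
with codes 1..N; parent 0 means unknown and a negative code names a genetic
group.  The data file holds, per record row, the level of every effect (0 =
absent) followed by the trait values in model order; a ranking trait takes
two columns (event id, finishing position), and 0 marks a missing value.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import (
    ConfigurationError,
    DataError,
    DataTable,
    EffectSpec,
    EventTable,
    McmcConfig,
    ModelSpec,
    TraitSpec,
    build_event_table,
)
from .pedigree import PedigreeTable

_SIMPLE_KEYS = {
    "DATAFILE", "PEDIGREEFILE", "NTRAITS", "EVENT_EFFECT",
    "NITER", "NBURNIN", "THIN", "SEED", "RANKING_RESIDUAL_VAR",
    "G_PRIOR_DF", "G_PRIOR_SCALE", "P_PRIOR_DF", "P_PRIOR_SCALE",
    "R_PRIOR_DF", "R_PRIOR_SCALE",
}
_TRAIT_RE = re.compile(r"^TRAIT(\d+)_(KIND|NCAT)$")
_EFFECT_RE = re.compile(r"^EFFECT(\d+)_(NAME|CLASS|NLEVELS|TRAITS)$")


@dataclass
class RunInputs:
    """Paths and optional priors resolved from a parameter file."""

    data_path: Path
    pedigree_path: Path
    priors: dict[str, tuple[float, np.ndarray]] = field(default_factory=dict)


def _read_kv(path: Path) -> dict[str, str]:
    kv: dict[str, str] = {}
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigurationError(f"{path}:{ln}: expected 'KEY = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        key = key.upper()
        if key in kv:
            raise ConfigurationError(f"{path}:{ln}: duplicate key {key}")
        kv[key] = val
    return kv


def _require(kv: dict[str, str], key: str) -> str:
    if key not in kv:
        raise ConfigurationError(f"missing mandatory parameter key {key}")
    return kv[key]


def parse_parameters(path: str | Path) -> tuple[ModelSpec, McmcConfig, RunInputs]:
    """Parse and validate a parameter file."""
    path = Path(path)
    kv = _read_kv(path)
    for key in kv:
        if key not in _SIMPLE_KEYS and not _TRAIT_RE.match(key) and not _EFFECT_RE.match(key):
            raise ConfigurationError(f"unknown parameter key {key}")

    n_traits = int(_require(kv, "NTRAITS"))
    resvar = float(kv.get("RANKING_RESIDUAL_VAR", "1.0"))
    traits = []
    for i in range(1, n_traits + 1):
        kind = _require(kv, f"TRAIT{i}_KIND").lower()
        if kind not in ("continuous", "threshold", "ranking"):
            raise ConfigurationError(
                f"TRAIT{i}_KIND must be continuous, threshold or ranking, got {kind!r}"
            )
        ncat = int(kv[f"TRAIT{i}_NCAT"]) if f"TRAIT{i}_NCAT" in kv else None
        traits.append(
            TraitSpec(
                name=f"trait{i}",
                kind=kind,
                n_categories=ncat,
                residual_variance=(
                    resvar if kind == "ranking" else 1.0 if kind == "threshold" else None
                ),
            )
        )
    n_effects = 0
    while f"EFFECT{n_effects + 1}_NAME" in kv:
        n_effects += 1
    if n_effects == 0:
        raise ConfigurationError("missing mandatory parameter key EFFECT1_NAME")
    event_raw = kv.get("EVENT_EFFECT", "NONE").upper()
    event_idx = None if event_raw == "NONE" else int(event_raw) - 1
    effects = []
    for j in range(1, n_effects + 1):
        tr = tuple(
            int(s) - 1 for s in re.split(r"[,\s]+", _require(kv, f"EFFECT{j}_TRAITS").strip())
        )
        effects.append(
            EffectSpec(
                name=_require(kv, f"EFFECT{j}_NAME"),
                kind=_require(kv, f"EFFECT{j}_CLASS").lower(),
                n_levels=int(_require(kv, f"EFFECT{j}_NLEVELS")),
                traits=tr,
                is_event_effect=(event_idx == j - 1),
            )
        )
    if event_idx is not None and not 0 <= event_idx < n_effects:
        raise ConfigurationError(f"EVENT_EFFECT index {event_idx + 1} out of range")
    model = ModelSpec(traits=traits, effects=effects)
    mcmc = McmcConfig(
        n_iterations=int(_require(kv, "NITER")),
        n_burnin=int(_require(kv, "NBURNIN")),
        thin=int(kv.get("THIN", "1")),
        seed=int(kv.get("SEED", "0")),
    )
    priors = {}
    for name in ("G", "P", "R"):
        if f"{name}_PRIOR_DF" in kv or f"{name}_PRIOR_SCALE" in kv:
            df = float(_require(kv, f"{name}_PRIOR_DF"))
            flat = np.array(
                [float(s) for s in _require(kv, f"{name}_PRIOR_SCALE").split()]
            )
            dim = int(round(np.sqrt(flat.size)))
            if dim * dim != flat.size:
                raise ConfigurationError(f"{name}_PRIOR_SCALE is not a square matrix")
            priors[name] = (df, flat.reshape(dim, dim))
    inputs = RunInputs(
        data_path=path.parent / _require(kv, "DATAFILE"),
        pedigree_path=path.parent / _require(kv, "PEDIGREEFILE"),
        priors=priors,
    )
    return model, mcmc, inputs


def read_pedigree(path: str | Path) -> PedigreeTable:
    """Read ``individual sire dam`` triples; codes need not be pre-sorted."""
    arr = np.loadtxt(path, dtype=np.int64, ndmin=2)
    if arr.shape[1] != 3:
        raise DataError(f"pedigree file needs 3 columns, found {arr.shape[1]}")
    n = arr.shape[0]
    ids = arr[:, 0]
    if not np.array_equal(np.sort(ids), np.arange(1, n + 1)):
        raise DataError("pedigree individuals must be coded exactly 1..N")
    sire = np.zeros(n, dtype=np.int64)
    dam = np.zeros(n, dtype=np.int64)
    sire[ids - 1] = arr[:, 1]
    dam[ids - 1] = arr[:, 2]
    return PedigreeTable(sire=sire, dam=dam)


def write_pedigree(path: str | Path, ped: PedigreeTable) -> None:
    with open(path, "w") as fh:
        for i in range(ped.n_individuals):
            fh.write(f"{i + 1} {ped.sire[i]} {ped.dam[i]}\n")


def trait_column_count(model: ModelSpec) -> int:
    return sum(2 if tr.kind == "ranking" else 1 for tr in model.traits)


def read_data(path: str | Path, model: ModelSpec) -> tuple[DataTable, EventTable]:
    """Read a data file and group ranking records into events."""
    arr = np.loadtxt(path, dtype=np.float64, ndmin=2)
    ncol = model.n_effects + trait_column_count(model)
    if arr.shape[1] != ncol:
        raise DataError(
            f"data file has {arr.shape[1]} columns; the model needs {ncol} "
            f"({model.n_effects} effect levels + trait columns)"
        )
    n = arr.shape[0]
    levels = arr[:, : model.n_effects]
    if np.any(levels != np.round(levels)) or np.any(levels < 0):
        raise DataError("effect levels must be non-negative integers")
    values = np.full((n, model.n_traits), np.nan)
    event_ids = np.zeros((n, model.n_traits), dtype=np.int64)
    positions = np.zeros((n, model.n_traits), dtype=np.int64)
    c = model.n_effects
    for q, tr in enumerate(model.traits):
        if tr.kind == "ranking":
            event_ids[:, q] = arr[:, c].astype(np.int64)
            positions[:, q] = arr[:, c + 1].astype(np.int64)
            c += 2
        else:
            v = arr[:, c]
            values[:, q] = np.where(v == 0, np.nan, v)
            c += 1
    data = DataTable(
        levels=levels.astype(np.int64), values=values,
        event_ids=event_ids, positions=positions,
    )
    data.check_against_model(model)
    return data, build_event_table(data, model)


def write_data(path: str | Path, data: DataTable, model: ModelSpec) -> None:
    """Write a data table in the layout ``read_data`` expects (0 = missing)."""
    with open(path, "w") as fh:
        for r in range(data.n_rows):
            parts = [str(int(v)) for v in data.levels[r]]
            for q, tr in enumerate(model.traits):
                if tr.kind == "ranking":
                    parts.append(str(int(data.event_ids[r, q])))
                    parts.append(str(int(data.positions[r, q])))
                else:
                    v = data.values[r, q]
                    parts.append("0" if np.isnan(v) else f"{v:.10g}")
            fh.write(" ".join(parts) + "\n")


def write_parameters(
    path: str | Path,
    model: ModelSpec,
    mcmc: McmcConfig,
    datafile: str,
    pedigreefile: str,
) -> None:
    """Write a parameter file describing ``model`` and ``mcmc``."""
    lines = [
        f"DATAFILE = {datafile}",
        f"PEDIGREEFILE = {pedigreefile}",
        f"NTRAITS = {model.n_traits}",
    ]
    for i, tr in enumerate(model.traits, start=1):
        lines.append(f"TRAIT{i}_KIND = {tr.kind}")
        if tr.kind == "threshold":
            lines.append(f"TRAIT{i}_NCAT = {tr.n_categories}")
    for j, eff in enumerate(model.effects, start=1):
        lines.append(f"EFFECT{j}_NAME = {eff.name}")
        lines.append(f"EFFECT{j}_CLASS = {eff.kind}")
        lines.append(f"EFFECT{j}_NLEVELS = {eff.n_levels}")
        lines.append(f"EFFECT{j}_TRAITS = " + " ".join(str(q + 1) for q in eff.traits))
    ev = model.event_effect_index
    lines.append(f"EVENT_EFFECT = {ev + 1 if ev is not None else 'NONE'}")
    rv = [tr.residual_variance for tr in model.traits if tr.kind == "ranking"]
    if rv:
        lines.append(f"RANKING_RESIDUAL_VAR = {rv[0]:.10g}")
    lines += [
        f"NITER = {mcmc.n_iterations}",
        f"NBURNIN = {mcmc.n_burnin}",
        f"THIN = {mcmc.thin}",
        f"SEED = {mcmc.seed}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
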