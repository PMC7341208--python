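"""Posterior summaries, output files and truth-based validation.

Variance-component samples retained after burn-in are summarised by
posterior mean, SD and the 95% highest-posterior-density interval (shortest
contiguous interval on the sorted samples).  Derived quantities —
heritabilities, variance ratios and correlations — are computed per sample
and then summarised, never as ratios of summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelSpec


def hpd_interval(samples: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=np.float64))
    n = x.size
    if n == 0:
        raise ValueError("cannot compute an HPD interval from no samples")
    k = int(np.ceil(prob * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k - 1:] - x[: n - k + 1]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k - 1])


def _tri_indices(t: int):
    return [(i, j) for i in range(t) for j in range(i, t)]


def component_columns(model: ModelSpec, env_traits: tuple[int, ...]) -> list[str]:
    """Column labels of the variance-component sample stream."""
    t = model.n_traits
    cols = [f"G[{i + 1},{j + 1}]" for i, j in _tri_indices(t)]
    p = len(env_traits)
    cols += [
        f"P[{env_traits[i] + 1},{env_traits[j] + 1}]" for i, j in _tri_indices(p)
    ]
    cols += [f"R[{i + 1},{j + 1}]" for i, j in _tri_indices(t)]
    return cols


def component_row(chain, env_traits: tuple[int, ...]) -> np.ndarray:
    """Current G/P/R upper triangles, in ``component_columns`` order."""
    t = chain.n_traits
    vals = [chain.G[i, j] for i, j in _tri_indices(t)]
    vals += [chain.P[i, j] for i, j in _tri_indices(len(env_traits))]
    vals += [chain.R[i, j] for i, j in _tri_indices(t)]
    return np.array(vals)


@dataclass
class PosteriorSummary:
    """Post-burn-in summary of the variance components and derived ratios.

    ``table`` has one row per parameter (components, heritabilities,
    variance ratios, correlations) with posterior mean, SD and the 95% HPD.
    ``derived`` holds the per-sample derived quantities used to build it.
    """

    table: pd.DataFrame
    derived: pd.DataFrame
    components: pd.DataFrame

    def covariance_mean(self, prefix: str, dim: int) -> np.ndarray:
        """Posterior-mean covariance matrix reassembled from the summary."""
        out = np.zeros((dim, dim))
        labels = [c for c in self.components.columns if c.startswith(prefix + "[")]
        pairs = {c: tuple(int(v) for v in c[c.index("[") + 1:-1].split(",")) for c in labels}
        if prefix == "P":
            # P columns are labelled by original trait indices; remap densely
            seen = sorted({v for pair in pairs.values() for v in pair})
            remap = {v: i for i, v in enumerate(seen)}
        for c in labels:
            i, j = pairs[c]
            if prefix == "P":
                i, j = remap[i], remap[j]
            else:
                i, j = i - 1, j - 1
            out[i, j] = out[j, i] = self.components[c].mean()
        return out

    def value(self, parameter: str, stat: str = "mean") -> float:
        return float(self.table.loc[parameter, stat])

    def hpd(self, parameter: str) -> tuple[float, float]:
        row = self.table.loc[parameter]
        return float(row["hpd95_low"]), float(row["hpd95_high"])

    def contains(self, parameter: str, true_value: float) -> bool:
        lo, hi = self.hpd(parameter)
        return lo <= true_value <= hi


def derived_samples(
    components: pd.DataFrame, model: ModelSpec, env_traits: tuple[int, ...]
) -> pd.DataFrame:
    """Per-sample heritabilities, variance ratios and correlations."""
    t = model.n_traits
    out = {}
    envset = set(env_traits)

    def col(prefix, i, j):
        i, j = min(i, j), max(i, j)
        return components[f"{prefix}[{i + 1},{j + 1}]"].to_numpy()

    for q in range(t):
        name = model.traits[q].name
        g = col("G", q, q)
        r = col("R", q, q)
        p = col("P", q, q) if q in envset else 0.0
        tot = g + p + r
        out[f"h2_{name}"] = g / tot
        out[f"ratio_a_{name}"] = g / tot
        if q in envset:
            out[f"ratio_pe_{name}"] = p / tot
        out[f"ratio_e_{name}"] = r / tot
    for i in range(t):
        for j in range(i + 1, t):
            ni, nj = model.traits[i].name, model.traits[j].name
            out[f"r_g_{ni}_{nj}"] = col("G", i, j) / np.sqrt(
                col("G", i, i) * col("G", j, j)
            )
            out[f"r_e_{ni}_{nj}"] = col("R", i, j) / np.sqrt(
                col("R", i, i) * col("R", j, j)
            )
            if i in envset and j in envset:
                out[f"r_pe_{ni}_{nj}"] = col("P", i, j) / np.sqrt(
                    col("P", i, i) * col("P", j, j)
                )
    return pd.DataFrame(out)


def summarize_chain(
    components: pd.DataFrame, model: ModelSpec, env_traits: tuple[int, ...] = ()
) -> PosteriorSummary:
    """Posterior means/SDs/95% HPDs of components and derived quantities."""
    if len(components) < 2:
        raise ValueError("need at least two retained samples to summarise a chain")
    derived = derived_samples(components, model, env_traits)
    both = pd.concat([components, derived], axis=1)
    rows = []
    for c in both.columns:
        x = both[c].to_numpy()
        lo, hi = hpd_interval(x)
        rows.append((c, x.mean(), x.std(ddof=1), lo, hi))
    table = pd.DataFrame(
        rows, columns=["parameter", "mean", "sd", "hpd95_low", "hpd95_high"]
    ).set_index("parameter")
    return PosteriorSummary(table=table, derived=derived, components=components)


def breeding_value_table(
    model: ModelSpec, mean_a: np.ndarray, sd_a: np.ndarray, n_individuals: int
) -> pd.DataFrame:
    """Posterior mean/SD of breeding values, one row per real individual."""
    out = {"individual": np.arange(1, n_individuals + 1)}
    for q, tr in enumerate(model.traits):
        out[f"ebv_{tr.name}"] = mean_a[:n_individuals, q]
        out[f"sd_{tr.name}"] = sd_a[:n_individuals, q]
    return pd.DataFrame(out)


def solution_table(
    model: ModelSpec, means: list[np.ndarray], sds: list[np.ndarray]
) -> pd.DataFrame:
    """Posterior mean/SD of systematic and environmental effect solutions."""
    recs = []
    for j, eff in enumerate(model.effects):
        if eff.kind == "additive_genetic":
            continue
        for q in eff.traits:
            for m in range(eff.n_levels):
                recs.append(
                    (eff.name, m + 1, model.traits[q].name,
                     means[j][m, q], sds[j][m, q])
                )
    return pd.DataFrame(recs, columns=["effect", "level", "trait", "mean", "sd"])


def write_outputs(out_dir: str | Path, estimator) -> dict[str, Path]:
    """Write Results.txt, Breeding.txt, Solutions.txt and Iterations.txt."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": out / "Results.txt",
        "breeding": out / "Breeding.txt",
        "solutions": out / "Solutions.txt",
        "iterations": out / "Iterations.txt",
    }
    estimator.summary_.table.reset_index().to_csv(
        paths["results"], sep="\t", index=False, float_format="%.6g"
    )
    estimator.breeding_values_.to_csv(
        paths["breeding"], sep="\t", index=False, float_format="%.6g"
    )
    estimator.solutions_.to_csv(
        paths["solutions"], sep="\t", index=False, float_format="%.6g"
    )
    estimator.samples_.to_csv(
        paths["iterations"], sep="\t", index=False, float_format="%.8g"
    )
    return paths


@dataclass
class ValidationReport:
    """Agreement between a fitted model and simulation truth.

    ``ebv_correlations`` maps trait name to the Pearson correlation between
    posterior-mean and true breeding values over individuals with records;
    ``event_effect_correlation`` correlates estimated event effects with the
    per-event mean true additive liability; ``coverage`` flags whether each
    supplied true parameter falls inside its 95% HPD interval.
    """

    ebv_correlations: dict[str, float]
    event_effect_correlation: float | None
    coverage: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (f"ebv_correlation_{k}", v) for k, v in self.ebv_correlations.items()
        ]
        if self.event_effect_correlation is not None:
            rows.append(("event_effect_correlation", self.event_effect_correlation))
        for k, v in self.coverage.items():
            rows.append((f"hpd95_covers_{k}", float(v)))
        return pd.DataFrame(rows, columns=["quantity", "value"])


def validate_against_truth(
    estimator,
    true_bv: np.ndarray,
    individuals: np.ndarray | None = None,
    true_event_means: np.ndarray | None = None,
    true_parameters: dict[str, float] | None = None,
) -> ValidationReport:
    """Correlate predictions with simulation truth and check HPD coverage.

    Parameters
    ----------
    true_bv : (N, t) true breeding values by individual code (1..N).
    individuals : codes of the individuals to correlate over (defaults to
        all individuals with records in the fitted data).
    true_event_means : per-event mean true additive liability, aligned with
        the event-effect levels 1..K.
    true_parameters : mapping of summary parameter names (e.g. ``h2_liability``
        or ``G[1,1]``) to their simulated values.
    """
    model = estimator.model
    true_bv = np.asarray(true_bv, dtype=np.float64)
    chain = estimator.chain_
    if individuals is None:
        j = model.additive_index
        with_records = np.unique(chain._lev_of[j])
        individuals = with_records[with_records < chain.ainv.n_individuals] + 1
    individuals = np.asarray(individuals, dtype=np.int64)
    if true_bv.shape[0] < individuals.max():
        raise ValueError(
            f"truth table has {true_bv.shape[0]} individuals, "
            f"data references code {individuals.max()}"
        )
    ebv = {}
    for q, tr in enumerate(model.traits):
        est = estimator.effect_means_[model.additive_index][individuals - 1, q]
        ebv[tr.name] = float(np.corrcoef(est, true_bv[individuals - 1, q])[0, 1])

    ev_corr = None
    if true_event_means is not None and model.event_effect_index is not None:
        j = model.event_effect_index
        q = model.effects[j].traits[0]
        est_ev = estimator.effect_means_[j][:, q]
        true_event_means = np.asarray(true_event_means, dtype=np.float64)
        if est_ev.shape[0] != true_event_means.shape[0]:
            raise ValueError(
                f"{est_ev.shape[0]} event levels vs {true_event_means.shape[0]} "
                "true event means"
            )
        ev_corr = float(np.corrcoef(est_ev, true_event_means)[0, 1])

    coverage = {}
    if true_parameters:
        for name, val in true_parameters.items():
            coverage[name] = estimator.summary_.contains(name, val)
    return ValidationReport(
        ebv_correlations=ebv,
        event_effect_correlation=ev_corr,
        coverage=coverage,
    )
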