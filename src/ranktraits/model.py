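"""Model description and in-memory data containers.

A model is a list of traits (continuous, threshold or ranking) plus a list of
effects (systematic, random environmental, additive genetic) with the traits
each effect applies to.  Ranking traits are observed as finishing positions
within competition events and are modelled through a latent Gaussian liability;
threshold traits through a latent liability cut at thresholds.  Both carry a
fixed residual variance on the liability scale, since the scale of a latent
variable is not identifiable from ordinal data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONTINUOUS = "continuous"
THRESHOLD = "threshold"
RANKING = "ranking"
TRAIT_KINDS = (CONTINUOUS, THRESHOLD, RANKING)

SYSTEMATIC = "systematic"
RANDOM_ENV = "random_environmental"
ADDITIVE = "additive_genetic"
EFFECT_CLASSES = (SYSTEMATIC, RANDOM_ENV, ADDITIVE)


class ConfigurationError(ValueError):
    """Invalid model, parameter file, or sampler configuration."""


class DataError(ValueError):
    """Invalid data file content (ties, bad categories, bad levels...)."""


class PedigreeError(ValueError):
    """Invalid pedigree (cycles, dangling parent codes...)."""


@dataclass(frozen=True)
class TraitSpec:
    """One trait of the multivariate model.

    Parameters
    ----------
    name : str
        Label used in output files.
    kind : {"continuous", "threshold", "ranking"}
    n_categories : int, optional
        Number of ordered categories; threshold traits only, >= 2.
    residual_variance : float, optional
        Fixed residual variance on the liability scale.  Mandatory for
        ranking and threshold traits (default 1.0), forbidden for
        continuous traits.
    """

    name: str
    kind: str
    n_categories: int | None = None
    residual_variance: float | None = None

    def __post_init__(self):
        if self.kind not in TRAIT_KINDS:
            raise ConfigurationError(
                f"trait {self.name!r}: kind must be one of {TRAIT_KINDS}, got {self.kind!r}"
            )
        if self.kind == THRESHOLD:
            if self.n_categories is None or self.n_categories < 2:
                raise ConfigurationError(
                    f"trait {self.name!r}: threshold traits need n_categories >= 2"
                )
        elif self.n_categories is not None:
            raise ConfigurationError(
                f"trait {self.name!r}: n_categories only applies to threshold traits"
            )
        if self.kind in (RANKING, THRESHOLD):
            if self.residual_variance is None:
                object.__setattr__(self, "residual_variance", 1.0)
            if self.residual_variance <= 0:
                raise ConfigurationError(
                    f"trait {self.name!r}: fixed residual variance must be > 0"
                )
        elif self.residual_variance is not None:
            raise ConfigurationError(
                f"trait {self.name!r}: continuous traits estimate their residual "
                "variance; do not fix it"
            )

    @property
    def is_latent(self) -> bool:
        """Whether the working value for this trait is a latent liability."""
        return self.kind in (RANKING, THRESHOLD)


@dataclass(frozen=True)
class EffectSpec:
    """One effect of the model.

    ``traits`` holds 0-based indices of the traits the effect applies to.
    ``is_event_effect`` marks the systematic effect whose levels are
    competition events; it may only act on ranking traits.
    """

    name: str
    kind: str
    n_levels: int
    traits: tuple[int, ...]
    is_event_effect: bool = False

    def __post_init__(self):
        if self.kind not in EFFECT_CLASSES:
            raise ConfigurationError(
                f"effect {self.name!r}: class must be one of {EFFECT_CLASSES}"
            )
        if self.n_levels < 1:
            raise ConfigurationError(f"effect {self.name!r}: n_levels must be >= 1")
        if self.is_event_effect and self.kind != SYSTEMATIC:
            raise ConfigurationError(
                f"effect {self.name!r}: only a systematic effect can be the event effect"
            )
        object.__setattr__(self, "traits", tuple(sorted(set(self.traits))))
        if not self.traits:
            raise ConfigurationError(f"effect {self.name!r}: applies to no trait")


@dataclass
class ModelSpec:
    """Traits plus effects; validates the joint layout."""

    traits: list[TraitSpec]
    effects: list[EffectSpec]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        t = len(self.traits)
        if t == 0:
            raise ConfigurationError("model needs at least one trait")
        for eff in self.effects:
            for q in eff.traits:
                if not 0 <= q < t:
                    raise ConfigurationError(
                        f"effect {eff.name!r} refers to trait index {q}, "
                        f"model has {t} traits"
                    )
        additive = [e for e in self.effects if e.kind == ADDITIVE]
        if len(additive) != 1:
            raise ConfigurationError(
                f"model needs exactly one additive genetic effect, found {len(additive)}"
            )
        if set(additive[0].traits) != set(range(t)):
            raise ConfigurationError(
                "the additive genetic effect must apply to every trait"
            )
        for eff in self.effects:
            if eff.is_event_effect:
                bad = [q for q in eff.traits if self.traits[q].kind != RANKING]
                if bad:
                    raise ConfigurationError(
                        f"event effect {eff.name!r} may only apply to ranking traits"
                    )
        constrained = [i for i, tr in enumerate(self.traits) if tr.is_latent]
        if t > 1 and len(constrained) > 1:
            raise ConfigurationError(
                "at most one trait with a fixed residual variance (ranking or "
                "threshold) is supported in a multivariate residual matrix"
            )

    # -- convenience views -------------------------------------------------
    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def n_effects(self) -> int:
        return len(self.effects)

    @property
    def additive_index(self) -> int:
        return next(i for i, e in enumerate(self.effects) if e.kind == ADDITIVE)

    @property
    def event_effect_index(self) -> int | None:
        for i, e in enumerate(self.effects):
            if e.is_event_effect:
                return i
        return None

    @property
    def ranking_traits(self) -> list[int]:
        return [i for i, tr in enumerate(self.traits) if tr.kind == RANKING]

    @property
    def threshold_traits(self) -> list[int]:
        return [i for i, tr in enumerate(self.traits) if tr.kind == THRESHOLD]

    @property
    def constrained_traits(self) -> list[int]:
        return [i for i, tr in enumerate(self.traits) if tr.is_latent]


@dataclass(frozen=True)
class McmcConfig:
    """Length of the Gibbs chain: total iterations, burn-in, thinning, seed."""

    n_iterations: int
    n_burnin: int
    thin: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ConfigurationError("n_iterations must be positive")
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ConfigurationError(
                f"n_burnin must satisfy 0 <= n_burnin < n_iterations "
                f"(got {self.n_burnin} vs {self.n_iterations})"
            )
        if self.thin < 1:
            raise ConfigurationError("thin must be >= 1")

    @property
    def n_retained(self) -> int:
        return self.n_iterations - self.n_burnin


@dataclass
class DataTable:
    """Record-per-row data.

    ``levels[r, j]`` is the 1-based level of effect j on row r, 0 when the
    effect is absent for that row.  ``values[r, q]`` is the observation for
    trait q (category number for threshold traits), NaN when missing or when
    the trait is a ranking liability.  Ranking traits carry instead an event
    id and a finishing position (0 = no record).
    """

    levels: np.ndarray
    values: np.ndarray
    event_ids: np.ndarray
    positions: np.ndarray

    def __post_init__(self):
        self.levels = np.ascontiguousarray(self.levels, dtype=np.int64)
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        self.event_ids = np.ascontiguousarray(self.event_ids, dtype=np.int64)
        self.positions = np.ascontiguousarray(self.positions, dtype=np.int64)
        n, _ = self.levels.shape
        for arr, name in ((self.values, "values"), (self.event_ids, "event_ids"),
                          (self.positions, "positions")):
            if arr.shape[0] != n:
                raise DataError(f"{name} has {arr.shape[0]} rows, levels has {n}")

    @property
    def n_rows(self) -> int:
        return self.levels.shape[0]

    @property
    def n_traits(self) -> int:
        return self.values.shape[1]

    def check_against_model(self, model: ModelSpec) -> None:
        if self.levels.shape[1] != model.n_effects:
            raise DataError(
                f"data has {self.levels.shape[1]} effect columns, "
                f"model declares {model.n_effects} effects"
            )
        if self.values.shape[1] != model.n_traits:
            raise DataError(
                f"data has {self.values.shape[1]} trait columns, "
                f"model declares {model.n_traits} traits"
            )
        for j, eff in enumerate(model.effects):
            col = self.levels[:, j]
            if col.min(initial=0) < 0 or col.max(initial=0) > eff.n_levels:
                raise DataError(
                    f"effect {eff.name!r}: level codes must lie in 0..{eff.n_levels}"
                )
        for q, tr in enumerate(model.traits):
            if tr.kind == THRESHOLD:
                v = self.values[:, q]
                obs = v[~np.isnan(v)]
                if obs.size and (obs.min() < 1 or obs.max() > tr.n_categories
                                 or np.any(obs != np.round(obs))):
                    raise DataError(
                        f"trait {tr.name!r}: categories must be integers in "
                        f"1..{tr.n_categories}"
                    )


@dataclass
class TraitEvents:
    """Rank constraints for one ranking trait, in CSR-like layout.

    ``rows[offsets[k]:offsets[k+1]]`` are the data rows of event k, sorted by
    finishing position (best first).  Gaps in positions are allowed; adjacency
    for truncation bounds follows this sort order, not the raw integers.
    """

    trait: int
    codes: np.ndarray      # (K,) original event ids
    offsets: np.ndarray    # (K+1,)
    rows: np.ndarray       # (m,) data-row indices, position-sorted per event
    positions: np.ndarray  # (m,) finishing positions aligned with ``rows``

    @property
    def n_events(self) -> int:
        return self.codes.shape[0]

    def event_rows(self, k: int) -> np.ndarray:
        return self.rows[self.offsets[k]:self.offsets[k + 1]]


@dataclass
class EventTable:
    """Per-ranking-trait event structures, keyed by trait index."""

    by_trait: dict[int, TraitEvents] = field(default_factory=dict)

    def __getitem__(self, trait: int) -> TraitEvents:
        return self.by_trait[trait]

    def __contains__(self, trait: int) -> bool:
        return trait in self.by_trait

    @property
    def n_events(self) -> int:
        return sum(te.n_events for te in self.by_trait.values())


def build_event_table(data: DataTable, model: ModelSpec) -> EventTable:
    """Group ranking records into events and check the rank invariants."""
    table = EventTable()
    for q in model.ranking_traits:
        ev = data.event_ids[:, q]
        pos = data.positions[:, q]
        has = ev > 0
        if np.any(has & (pos <= 0)):
            raise DataError(
                f"trait {model.traits[q].name!r}: ranked rows need a positive "
                "finishing position"
            )
        if np.any((~has) & (pos > 0)):
            raise DataError(
                f"trait {model.traits[q].name!r}: a finishing position without "
                "an event id"
            )
        idx = np.flatnonzero(has)
        order = idx[np.lexsort((pos[idx], ev[idx]))]
        ev_s, pos_s = ev[order], pos[order]
        codes, starts = np.unique(ev_s, return_index=True)
        offsets = np.append(starts, ev_s.size)
        # ties: same event, same position -> adjacent after the sort
        dup = (np.diff(ev_s) == 0) & (np.diff(pos_s) == 0)
        if np.any(dup):
            j = int(np.flatnonzero(dup)[0])
            raise DataError(
                f"trait {model.traits[q].name!r}: tied finishing position "
                f"{pos_s[j]} in event {ev_s[j]}; ties are not supported"
            )
        table.by_trait[q] = TraitEvents(
            trait=q, codes=codes, offsets=offsets, rows=order, positions=pos_s
        )
    return table
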