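"""Gibbs sampler for the Thurstonian animal model.

Ranks observed in competition events are modelled as the ordering of latent
Gaussian liabilities.  Writing l for the liability of one start and y for the
correlated continuous trait(s), a record row follows

    (l, y) ~ MVN( (x_l' b_l + z_l' a_l,  x_y' b_y + z_y' a_y),  R )

with additive genetic effects a ~ MVN(0, G ⊗ A) and, optionally, permanent
environmental effects ~ MVN(0, P ⊗ I).  The residual variance of a liability
is not identifiable from ranks and is held fixed (1 by default).

Each Gibbs iteration augments missing records, redraws the liabilities event
by event under the observed rank order T_k (the winner's liability is pinned
at 0 for identifiability and an "event" effect is estimated instead), redraws
all location effects from their Gaussian full conditionals, and redraws
G, P and R from inverted-Wishart full conditionals — R under its fixed-element
constraint.

The estimator :class:`ThurstonianGibbsSampler` wraps the chain in the
scikit-learn fit idiom; :class:`GibbsChain` exposes the individual conditional
updates for diagnostics and testing.
"""

from __future__ import annotations

from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import summaries as _summaries
from ._kernels import sample_additive_sweep
from .model import (
    RANDOM_ENV,
    ConfigurationError,
    DataTable,
    EventTable,
    McmcConfig,
    ModelSpec,
    build_event_table,
)
from .pedigree import AInverse, PedigreeTable, build_a_inverse
from .truncnorm import sample_truncnorm


class NumericalError(RuntimeError):
    """A covariance matrix lost positive definiteness during sampling."""


class IWPrior(NamedTuple):
    """Inverted-Wishart prior: density ∝ |Σ|^-(df+p+1)/2 exp(-tr(S Σ⁻¹)/2)."""

    df: float
    scale: np.ndarray


def flat_iw_prior(p: int) -> IWPrior:
    """Flat limiting form (df = -(p+1), S = 0): uniform on covariance matrices."""
    return IWPrior(df=-(p + 1.0), scale=np.zeros((p, p)))


def sample_invwishart(rng: np.random.Generator, scale: np.ndarray, df: float) -> np.ndarray:
    """Draw from IW(scale, df) by inverting a Bartlett-decomposed Wishart draw."""
    p = scale.shape[0]
    if df <= p - 1:
        raise NumericalError(
            f"inverted-Wishart degrees of freedom {df} too small for dimension {p}"
        )
    try:
        sinv = np.linalg.inv(scale)
        low = np.linalg.cholesky(sinv)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"inverted-Wishart scale matrix not PD: {exc}") from exc
    bart = np.zeros((p, p))
    for i in range(p):
        bart[i, i] = np.sqrt(rng.chisquare(df - i))
        for j in range(i):
            bart[i, j] = rng.standard_normal()
    f = low @ bart
    return np.linalg.inv(f @ f.T)


def conditional_liability_moments(
    R: np.ndarray, trait: int, pred: np.ndarray, resid: np.ndarray
) -> tuple[np.ndarray, float]:
    """Mean and variance of one liability given the row's other traits.

    With W = R⁻¹ the full conditional of trait ``trait`` on a row is Gaussian
    with variance sigma² = 1/W_ll and mean

        mu = x'b_l + z'a_l  -  sigma² * Σ_{q≠l} W_lq e_q,

    i.e. the precision-ratio form of the multivariate-normal conditional
    (W_lq/W_ll = -R_lq,others-form regression coefficient).

    Parameters
    ----------
    R : (t, t) residual covariance matrix.
    trait : index of the liability trait within R.
    pred : (n,) systematic + genetic predictor of the liability rows.
    resid : (n, t) residuals of all traits on those rows; the ``trait``
        column is ignored.

    Returns
    -------
    mu : (n,) conditional means; sigma2 : scalar conditional variance.
    """
    w = np.linalg.inv(R)
    sigma2 = 1.0 / w[trait, trait]
    s = resid @ w[:, trait] - w[trait, trait] * resid[:, trait]
    return np.asarray(pred) - sigma2 * s, sigma2


class _Slots(NamedTuple):
    """Rank-position slices of one ranking trait's events (vector sweep)."""

    cur: np.ndarray   # data rows at this rank position, one per live event
    up: np.ndarray    # rows ranked immediately above (empty at position 0)
    low: np.ndarray   # rows ranked immediately below; -1 = last position


class GibbsChain:
    """Mutable sampler state plus one method per conditional update.

    Holds the working response matrix ``Y`` (observed values, liabilities and
    augmented records), effect solutions ``sol`` (one (n_levels, t) array per
    effect; the additive one is augmented with genetic-group columns), the
    covariance matrices ``G``, ``P``, ``R``, threshold vectors, and the RNG.
    """

    def __init__(
        self,
        model: ModelSpec,
        data: DataTable,
        ainv: AInverse,
        events: EventTable | None = None,
        rng: np.random.Generator | int | None = None,
        g_prior: IWPrior | None = None,
        p_prior: IWPrior | None = None,
        r_prior: IWPrior | None = None,
    ):
        data.check_against_model(model)
        self.model = model
        self.data = data
        self.ainv = ainv
        self.events = build_event_table(data, model) if events is None else events
        self.rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

        t = model.n_traits
        n = data.n_rows
        self.n_traits, self.n_rows = t, n
        env = [j for j, e in enumerate(model.effects) if e.kind == RANDOM_ENV]
        if len(env) > 1:
            raise ConfigurationError(
                "at most one random environmental effect is supported"
            )
        self.env_index = env[0] if env else None
        self.additive_index = model.additive_index
        add = model.effects[self.additive_index]
        if add.n_levels != ainv.n_individuals:
            raise ConfigurationError(
                f"additive effect declares {add.n_levels} levels but the "
                f"pedigree has {ainv.n_individuals} individuals"
            )

        self.g_prior = g_prior if g_prior is not None else flat_iw_prior(t)
        env_dim = len(model.effects[self.env_index].traits) if env else 0
        self.p_prior = p_prior if p_prior is not None else flat_iw_prior(env_dim)
        self.r_prior = r_prior if r_prior is not None else flat_iw_prior(t)
        if model.constrained_traits and (
            r_prior is not None and (r_prior.df != -(t + 1) or np.any(r_prior.scale))
        ):
            raise ConfigurationError(
                "a proper residual prior is only supported when no trait has a "
                "fixed residual variance"
            )

        # ---- row bookkeeping -------------------------------------------
        lev0 = data.levels - 1  # -1 = effect absent on the row
        self._lev0 = lev0
        self._rows_of: list[np.ndarray] = []
        self._lev_of: list[np.ndarray] = []
        self._counts: list[np.ndarray] = []
        for j, eff in enumerate(model.effects):
            rows = np.flatnonzero(lev0[:, j] >= 0)
            lv = lev0[rows, j]
            self._rows_of.append(rows)
            self._lev_of.append(lv)
            nl = eff.n_levels + (ainv.n_groups if j == self.additive_index else 0)
            self._counts.append(np.bincount(lv, minlength=nl).astype(np.float64))
        # systematic levels never observed have zero precision under a flat
        # prior: they are left untouched and flagged
        self.skipped_levels = [
            (model.effects[j].name, int(m) + 1)
            for j in range(model.n_effects)
            if j not in (self.env_index, self.additive_index)
            for m in np.flatnonzero(self._counts[j][: model.effects[j].n_levels] == 0)
        ]

        # rank-position slot structure per ranking trait
        self._slots: dict[int, list[_Slots]] = {}
        for q in model.ranking_traits:
            te = self.events[q]
            sizes = np.diff(te.offsets)
            slots = []
            for r in range(int(sizes.max(initial=0))):
                live = np.flatnonzero(sizes > r)
                start = te.offsets[live]
                cur = te.rows[start + r]
                up = te.rows[start + r - 1] if r > 0 else np.empty(0, dtype=np.int64)
                low = np.full(live.size, -1, dtype=np.int64)
                deeper = sizes[live] > r + 1
                low[deeper] = te.rows[start[deeper] + r + 1]
                slots.append(_Slots(cur=cur, up=up, low=low))
            self._slots[q] = slots

        # missingness: cells to augment each iteration
        miss = np.isnan(data.values)
        for q in model.ranking_traits:
            miss[:, q] = data.event_ids[:, q] == 0
        for q in model.threshold_traits:
            miss[:, q] = np.isnan(data.values[:, q])
        self._missing = miss
        self._patterns = []
        if miss.any():
            pat, inv = np.unique(miss, axis=0, return_inverse=True)
            for k in range(pat.shape[0]):
                if pat[k].any():
                    self._patterns.append((pat[k], np.flatnonzero(inv == k)))

        self._init_state()

    # ------------------------------------------------------------------
    def _init_state(self) -> None:
        model, data = self.model, self.data
        t, n = self.n_traits, self.n_rows
        Y = np.where(np.isnan(data.values), 0.0, data.values).astype(np.float64)
        # deterministic liability ladder: winner 0, each next rank 0.5 lower
        for q in model.ranking_traits:
            for r, slot in enumerate(self._slots[q]):
                Y[slot.cur, q] = -0.5 * r
        self.thresholds: dict[int, np.ndarray] = {}
        for q in model.threshold_traits:
            c = model.traits[q].n_categories
            thr = np.concatenate([[-np.inf, 0.0], 0.5 * np.arange(1, c - 1), [np.inf]])
            self.thresholds[q] = thr
            cat = data.values[:, q]
            obs = ~np.isnan(cat)
            mid = np.where(
                cat[obs] == 1, -0.5,
                np.where(cat[obs] == c, thr[c - 1] + 0.5,
                         0.5 * (thr[np.maximum(cat[obs].astype(int) - 1, 1)]
                                + thr[np.minimum(cat[obs].astype(int), c - 1)])),
            )
            Y[obs, q] = mid
        # fill missing continuous cells with the observed mean
        for q in range(t):
            m = self._missing[:, q]
            if m.any() and model.traits[q].kind == "continuous":
                obs = ~m
                Y[m, q] = Y[obs, q].mean() if obs.any() else 0.0
        self.Y = Y

        self.sol: list[np.ndarray] = []
        for j, eff in enumerate(model.effects):
            nl = eff.n_levels + (self.ainv.n_groups if j == self.additive_index else 0)
            self.sol.append(np.zeros((nl, t)))

        # split the raw variance of the initialised response equally among the
        # variance components of each trait
        ncomp = np.full(t, 2.0)  # additive + residual
        env_traits = ()
        if self.env_index is not None:
            env_traits = self.model.effects[self.env_index].traits
            for q in env_traits:
                ncomp[q] += 1.0
        raw = np.array([max(np.var(Y[:, q]), 1e-6) for q in range(t)])
        self.G = np.diag(raw / ncomp)
        self.R = np.diag(raw / ncomp)
        for q in model.constrained_traits:
            self.R[q, q] = model.traits[q].residual_variance
        self.P = np.diag(raw[list(env_traits)] / ncomp[list(env_traits)]) \
            if env_traits else np.zeros((0, 0))

    # ------------------------------------------------------------------
    @property
    def a(self) -> np.ndarray:
        """Additive genetic effects, (N + n_groups, t)."""
        return self.sol[self.additive_index]

    def predicted(self) -> np.ndarray:
        """Location predictor per row and trait (all effects summed)."""
        pred = np.zeros((self.n_rows, self.n_traits))
        for j, eff in enumerate(self.model.effects):
            rows, lv = self._rows_of[j], self._lev_of[j]
            for q in eff.traits:
                pred[rows, q] += self.sol[j][lv, q]
        return pred

    def residuals(self) -> np.ndarray:
        return self.Y - self.predicted()

    # ---- conditional updates -----------------------------------------
    def augment_missing(self, pred: np.ndarray, E: np.ndarray) -> None:
        """Replace missing cells by draws from their row-wise conditionals."""
        for patt, rows in self._patterns:
            mset = np.flatnonzero(patt)
            oset = np.flatnonzero(~patt)
            if oset.size:
                rmo = self.R[np.ix_(mset, oset)]
                slv = np.linalg.solve(self.R[np.ix_(oset, oset)], rmo.T).T
                cov = self.R[np.ix_(mset, mset)] - slv @ rmo.T
                mean = pred[np.ix_(rows, mset)] + E[np.ix_(rows, oset)] @ slv.T
            else:
                cov = self.R[np.ix_(mset, mset)]
                mean = pred[np.ix_(rows, mset)]
            low = np.linalg.cholesky(cov)
            draw = mean + self.rng.standard_normal(mean.shape) @ low.T
            for k, q in enumerate(mset):
                self.Y[rows, q] = draw[:, k]
                E[rows, q] = draw[:, k] - pred[rows, q]

    def sample_event_liabilities(self, trait: int, pred: np.ndarray, E: np.ndarray) -> None:
        """Redraw liabilities of one ranking trait under the rank order T_k.

        Within each event the winner's liability is set to 0 and ranks
        2..n are drawn in order from truncated normals bounded above by the
        just-updated liability of the preceding horse and below by the
        current liability of the horse ranked immediately after (-inf for
        the last).
        """
        mu, s2 = conditional_liability_moments(self.R, trait, pred[:, trait], E)
        sig = np.sqrt(s2)
        Yq = self.Y[:, trait]
        slots = self._slots[trait]
        if slots:
            Yq[slots[0].cur] = 0.0
        for r in range(1, len(slots)):
            cur, up, low = slots[r]
            upper = Yq[up[: cur.size]] if up.size else np.inf
            lower = np.where(low >= 0, Yq[np.maximum(low, 0)], -np.inf)
            Yq[cur] = sample_truncnorm(mu[cur], sig, lower, upper, self.rng)
        rows = self.events[trait].rows
        E[rows, trait] = Yq[rows] - pred[rows, trait]

    def sample_threshold_liabilities(self, trait: int, pred: np.ndarray, E: np.ndarray) -> None:
        """Redraw liabilities of a threshold trait within its category bands."""
        cat = self.data.values[:, trait]
        obs = np.flatnonzero(~np.isnan(cat))
        if obs.size == 0:
            return
        c = cat[obs].astype(int)
        thr = self.thresholds[trait]
        mu, s2 = conditional_liability_moments(self.R, trait, pred[:, trait], E)
        draw = sample_truncnorm(
            mu[obs], np.sqrt(s2), thr[c - 1], thr[c], self.rng
        )
        self.Y[obs, trait] = draw
        E[obs, trait] = draw - pred[obs, trait]
        ncat = self.model.traits[trait].n_categories
        if ncat > 2:
            # interior thresholds (t_1 = 0 stays fixed) between the extreme
            # liabilities of adjacent observed categories
            for k in range(2, ncat):
                below = draw[c == k]
                above = draw[c == k + 1]
                lo = below.max() if below.size else thr[k - 1]
                hi = above.min() if above.size else thr[k + 1]
                thr[k] = self.rng.uniform(lo, hi)

    def sample_location_effects(self, E: np.ndarray) -> None:
        """Gibbs draws for all systematic, environmental and additive effects.

        Systematic and environmental effects are updated single-site with
        residual-precision weighting across traits; additive effects are
        blocked per individual across traits (an exact scheme with better
        mixing).  ``E`` is kept consistent in place.
        """
        w = np.linalg.inv(self.R)
        ginv = np.linalg.inv(self.G)
        pinv = np.linalg.inv(self.P) if self.P.size else None
        for j, eff in enumerate(self.model.effects):
            if j == self.additive_index:
                continue
            rows, lv, cnt = self._rows_of[j], self._lev_of[j], self._counts[j]
            nl = eff.n_levels
            is_env = j == self.env_index
            for qi, q in enumerate(eff.traits):
                cur = self.sol[j][:, q]
                s = np.bincount(lv, weights=E[rows] @ w[:, q], minlength=nl)
                s += w[q, q] * cnt * cur
                prec = cnt * w[q, q]
                if is_env:
                    # prior N(0, P) across this effect's traits, single-site
                    env_sol = self.sol[j][:, list(eff.traits)]
                    s -= env_sol @ pinv[:, qi] - pinv[qi, qi] * cur
                    prec = prec + pinv[qi, qi]
                ok = prec > 0
                new = cur.copy()
                new[ok] = s[ok] / prec[ok] + self.rng.standard_normal(
                    int(ok.sum())
                ) / np.sqrt(prec[ok])
                E[rows, q] += cur[lv] - new[lv]
                self.sol[j][:, q] = new
        self._sample_additive(E, w, ginv)

    def _sample_additive(self, E: np.ndarray, w: np.ndarray, ginv: np.ndarray) -> None:
        j = self.additive_index
        rows, lv = self._rows_of[j], self._lev_of[j]
        a = self.sol[j]
        m = a.shape[0]
        wE = E[rows] @ w
        sw = np.empty_like(a)
        for q in range(self.n_traits):
            sw[:, q] = np.bincount(lv, weights=wE[:, q], minlength=m)
        sw += self._counts[j][:, None] * (a @ w)
        z = self.rng.standard_normal(a.shape)
        a_old = a.copy()
        mat = self.ainv.matrix
        sample_additive_sweep(
            mat.indptr, mat.indices, mat.data, a, ginv, w, sw, self._counts[j], z
        )
        E[rows] += a_old[lv] - a[lv]

    def sample_genetic_covariance(self) -> None:
        """G | a ~ IW(a'A⁻¹a + S0, N + df0) (Quaas–Westell augmented form)."""
        a = self.a
        scale = a.T @ (self.ainv.matrix @ a) + self.g_prior.scale
        df = self.ainv.n_individuals + self.g_prior.df
        self.G = sample_invwishart(self.rng, scale, df)

    def sample_environmental_covariance(self) -> None:
        if self.env_index is None:
            return
        eff = self.model.effects[self.env_index]
        u = self.sol[self.env_index][:, list(eff.traits)]
        scale = u.T @ u + self.p_prior.scale
        self.P = sample_invwishart(self.rng, scale, eff.n_levels + self.p_prior.df)

    def sample_residual_covariance(self, E: np.ndarray) -> None:
        """R | residuals, honouring fixed liability variances exactly.

        Without constrained traits this is a plain inverted-Wishart draw from
        the residual crossproducts.  With one constrained trait (variance v)
        R is decomposed into v, the regression b of the other traits on the
        liability residual, and their conditional covariance S; b and S have
        standard Gaussian / inverted-Wishart conditionals and R is
        reassembled with R_ll = v exact.
        """
        t, n = self.n_traits, E.shape[0]
        con = self.model.constrained_traits
        if not con:
            scale = E.T @ E + self.r_prior.scale
            self.R = sample_invwishart(self.rng, scale, n + self.r_prior.df)
            return
        if t == 1:
            return  # fully constrained: nothing to update
        c = con[0]
        o = [q for q in range(t) if q != c]
        v = self.model.traits[c].residual_variance
        el = E[:, c]
        eo = E[:, o]
        q2 = float(el @ el)
        bhat = (eo.T @ el) / q2
        dev = eo - np.outer(el, bhat)
        s_cond = sample_invwishart(self.rng, dev.T @ dev, n - len(o) - 1.0)
        low = np.linalg.cholesky(s_cond)
        b = bhat + (low @ self.rng.standard_normal(len(o))) / np.sqrt(q2)
        R = np.empty((t, t))
        R[c, c] = v
        R[np.ix_([c], o)] = b * v
        R[np.ix_(o, [c])] = (b * v)[:, None]
        R[np.ix_(o, o)] = s_cond + np.outer(b, b) * v
        self.R = R

    # ------------------------------------------------------------------
    def step(self) -> None:
        """One full Gibbs iteration in the canonical update order."""
        pred = self.predicted()
        E = self.Y - pred
        self.augment_missing(pred, E)
        for q in self.model.ranking_traits:
            self.sample_event_liabilities(q, pred, E)
        for q in self.model.threshold_traits:
            self.sample_threshold_liabilities(q, pred, E)
        self.sample_location_effects(E)
        self.sample_genetic_covariance()
        self.sample_environmental_covariance()
        self.sample_residual_covariance(E)

    def check_invariants(self, atol: float = 1e-9) -> None:
        """Assert the structural invariants of the chain state."""
        for q in self.model.constrained_traits:
            v = self.model.traits[q].residual_variance
            if self.R[q, q] != v:
                raise AssertionError(
                    f"fixed residual variance drifted: R[{q},{q}] = {self.R[q, q]} != {v}"
                )
        for name, mat in (("G", self.G), ("P", self.P), ("R", self.R)):
            if mat.size:
                np.linalg.cholesky(mat)
                if not np.allclose(mat, mat.T, atol=atol):
                    raise AssertionError(f"{name} not symmetric")
        for q in self.model.ranking_traits:
            te = self.events[q]
            for k in range(te.n_events):
                liab = self.Y[te.event_rows(k), q]
                if liab[0] != 0.0:
                    raise AssertionError("winner liability not zero")
                if np.any(np.diff(liab) > 0):
                    raise AssertionError("liabilities violate the rank order")


class ThurstonianGibbsSampler(BaseEstimator):
    """Bayesian Thurstonian animal model fitted by Gibbs sampling.

    Parameters
    ----------
    model : ModelSpec
        Trait and effect layout of the analysis.
    n_iterations, n_burnin, thin, seed : int
        Chain length (total, including burn-in), burn-in to discard,
        thinning interval for the stored variance-component samples, and
        RNG seed.
    g_prior, p_prior, r_prior : IWPrior, optional
        Proper inverted-Wishart priors; default is the flat limiting form.
    check_invariants : bool
        Assert the structural invariants after every iteration (slow; for
        validation runs).
    callback : callable, optional
        ``callback(chain, iteration)`` invoked after every iteration.

    Attributes
    ----------
    G_, P_, R_ : posterior means of the covariance matrices.
    samples_ : DataFrame of retained (thinned) variance-component samples.
    summary_ : PosteriorSummary with means/SDs/95% HPD intervals, including
        heritabilities, variance ratios and correlations.
    breeding_values_ : DataFrame (individual, trait, mean, sd).
    solutions_ : DataFrame of systematic/environmental effect solutions.
    """

    def __init__(
        self,
        model: ModelSpec | None = None,
        n_iterations: int = 20000,
        n_burnin: int = 4000,
        thin: int = 10,
        seed: int = 0,
        g_prior: IWPrior | None = None,
        p_prior: IWPrior | None = None,
        r_prior: IWPrior | None = None,
        check_invariants: bool = False,
        callback: Callable | None = None,
        verbose: bool = False,
    ):
        self.model = model
        self.n_iterations = n_iterations
        self.n_burnin = n_burnin
        self.thin = thin
        self.seed = seed
        self.g_prior = g_prior
        self.p_prior = p_prior
        self.r_prior = r_prior
        self.check_invariants = check_invariants
        self.callback = callback
        self.verbose = verbose

    # ------------------------------------------------------------------
    def fit(self, data: DataTable, pedigree: PedigreeTable | AInverse):
        """Run the chain on a data table and pedigree; returns self."""
        if self.model is None:
            raise ConfigurationError("ThurstonianGibbsSampler needs a ModelSpec")
        cfg = McmcConfig(self.n_iterations, self.n_burnin, self.thin, self.seed)
        ainv = pedigree if isinstance(pedigree, AInverse) else build_a_inverse(pedigree)
        chain = GibbsChain(
            self.model, data, ainv,
            rng=np.random.default_rng(cfg.seed),
            g_prior=self.g_prior, p_prior=self.p_prior, r_prior=self.r_prior,
        )
        model = self.model
        t = model.n_traits
        env_traits = (
            model.effects[chain.env_index].traits if chain.env_index is not None else ()
        )

        cols = _summaries.component_columns(model, env_traits)
        n_kept = (cfg.n_retained + cfg.thin - 1) // cfg.thin
        samples = np.empty((n_kept, len(cols)))
        sums = [np.zeros_like(s) for s in chain.sol]
        sqs = [np.zeros_like(s) for s in chain.sol]
        kept = 0
        n_acc = 0
        for it in range(cfg.n_iterations):
            chain.step()
            if self.callback is not None:
                self.callback(chain, it)
            if self.check_invariants:
                chain.check_invariants()
            if it < cfg.n_burnin:
                continue
            n_acc += 1
            for j in range(model.n_effects):
                sums[j] += chain.sol[j]
                sqs[j] += chain.sol[j] ** 2
            if (it - cfg.n_burnin) % cfg.thin == 0:
                samples[kept] = _summaries.component_row(chain, env_traits)
                kept += 1
            if self.verbose and (it + 1) % max(1, cfg.n_iterations // 20) == 0:
                print(f"iteration {it + 1}/{cfg.n_iterations}")

        self.chain_ = chain
        self.samples_ = pd.DataFrame(samples[:kept], columns=cols)
        self.summary_ = _summaries.summarize_chain(self.samples_, model, env_traits)
        self.G_ = self.summary_.covariance_mean("G", t)
        self.R_ = self.summary_.covariance_mean("R", t)
        self.P_ = (
            self.summary_.covariance_mean("P", len(env_traits))
            if env_traits else np.zeros((0, 0))
        )
        means = [s / n_acc for s in sums]
        sds = [
            np.sqrt(np.maximum(q / n_acc - m**2, 0.0))
            for q, m in zip(sqs, means)
        ]
        self.breeding_values_ = _summaries.breeding_value_table(
            model, means[model.additive_index], sds[model.additive_index],
            ainv.n_individuals,
        )
        self.solutions_ = _summaries.solution_table(model, means, sds)
        self.effect_means_ = means
        self.effect_sds_ = sds
        self.n_records_ = data.n_rows
        return self

    # convenience ------------------------------------------------------
    @property
    def event_effects_(self) -> pd.DataFrame:
        """Posterior means/SDs of the event effect, one row per event level."""
        j = self.model.event_effect_index
        if j is None:
            raise AttributeError("model has no event effect")
        sol = self.solutions_
        return sol[sol["effect"] == self.model.effects[j].name].reset_index(drop=True)

    def predict(self, individuals: np.ndarray | None = None, trait: int = 0) -> np.ndarray:
        """Posterior-mean breeding values (the selection criterion)."""
        bv = self.effect_means_[self.model.additive_index][:, trait]
        if individuals is None:
            return bv
        return bv[np.asarray(individuals) - 1]


def run_chain(
    model: ModelSpec,
    data: DataTable,
    pedigree: PedigreeTable | AInverse,
    config: McmcConfig,
    **kwargs,
) -> ThurstonianGibbsSampler:
    """Functional entry point: configure, fit and return the estimator."""
    est = ThurstonianGibbsSampler(
        model=model,
        n_iterations=config.n_iterations,
        n_burnin=config.n_burnin,
        thin=config.thin,
        seed=config.seed,
        **kwargs,
    )
    return est.fit(data, pedigree)
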