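"""Each Gibbs conditional update against an independent closed-form oracle."""

import numpy as np
import pytest
from scipy import stats

import ranktraits as rt
from conftest import founders_pedigree, make_chain, random_pedigree

HALF_NORMAL_MEAN = np.sqrt(2.0 / np.pi)


def continuous_model(n_ind, n_traits=1, with_mean=False):
    traits = [rt.TraitSpec(f"y{q + 1}", "continuous") for q in range(n_traits)]
    effects = []
    if with_mean:
        effects.append(rt.EffectSpec("mean", "systematic", 1, (0,)))
    effects.append(
        rt.EffectSpec("animal", "additive_genetic", n_ind, tuple(range(n_traits)))
    )
    return rt.ModelSpec(traits=traits, effects=effects)


def plain_data(n_rows, n_effects, values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != n_rows:
        values = values.T
    t = values.shape[1]
    return rt.DataTable(
        levels=np.zeros((n_rows, n_effects), dtype=np.int64),
        values=values,
        event_ids=np.zeros((n_rows, t), dtype=np.int64),
        positions=np.zeros((n_rows, t), dtype=np.int64),
    )


class TestConditionalLiabilityMoments:
    def test_univariate_independence(self):
        R = np.array([[1.0]])
        mu, s2 = rt.conditional_liability_moments(
            R, 0, np.array([0.3, -0.2]), np.array([[5.0], [1.0]])
        )
        np.testing.assert_allclose(mu, [0.3, -0.2])
        assert s2 == 1.0

    def test_bivariate_closed_form(self):
        # the validation study's residual structure
        cov = -0.2 * np.sqrt(2.0)
        R = np.array([[1.0, cov], [cov, 2.0]])
        rng = np.random.default_rng(0)
        pred = rng.normal(size=40)
        resid = rng.normal(size=(40, 2))
        mu, s2 = rt.conditional_liability_moments(R, 0, pred, resid)
        # covariance-form conditional: E[l | e_y] = pred + (s_ly/s_yy) e_y
        np.testing.assert_allclose(mu, pred + (cov / 2.0) * resid[:, 1], atol=1e-12)
        assert s2 == pytest.approx(1.0 - cov**2 / 2.0, abs=1e-12)

    def test_precision_identity_random_pd(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            t = rng.integers(2, 5)
            m = rng.normal(size=(t, t + 2))
            R = m @ m.T + 0.1 * np.eye(t)
            lt = int(rng.integers(t))
            resid = rng.normal(size=(6, t))
            mu, s2 = rt.conditional_liability_moments(R, lt, np.zeros(6), resid)
            o = [q for q in range(t) if q != lt]
            # independent route: Schur complement and covariance regression
            slv = np.linalg.solve(R[np.ix_(o, o)], R[np.ix_(o, [lt])]).ravel()
            np.testing.assert_allclose(
                s2, R[lt, lt] - R[lt, o] @ slv, rtol=1e-10
            )
            np.testing.assert_allclose(mu, resid[:, o] @ slv, atol=1e-10)


class TestEventLiabilities:
    @pytest.fixture
    def pair_chain(self):
        """5000 two-horse events with zero predictor and unit liability variance."""
        model = rt.ModelSpec(
            traits=[rt.TraitSpec("liab", "ranking")],
            effects=[rt.EffectSpec("animal", "additive_genetic", 2, (0,))],
        )
        k = 5000
        data = rt.DataTable(
            levels=np.zeros((2 * k, 1), dtype=np.int64),
            values=np.full((2 * k, 1), np.nan),
            event_ids=np.repeat(np.arange(1, k + 1), 2)[:, None],
            positions=np.tile([1, 2], k)[:, None],
        )
        return make_chain(model, data, founders_pedigree(2), seed=3)

    def test_single_competitor_event_pins_zero(self):
        model = rt.ModelSpec(
            traits=[rt.TraitSpec("liab", "ranking")],
            effects=[rt.EffectSpec("animal", "additive_genetic", 1, (0,))],
        )
        data = rt.DataTable(
            levels=np.zeros((1, 1), dtype=np.int64),
            values=np.full((1, 1), np.nan),
            event_ids=np.array([[4]]), positions=np.array([[1]]),
        )
        chain = make_chain(model, data, founders_pedigree(1))
        pred = chain.predicted()
        chain.sample_event_liabilities(0, pred, chain.Y - pred)
        assert chain.Y[0, 0] == 0.0

    def test_runner_up_is_half_normal(self, pair_chain):
        """Rank 2 of a two-horse event: TN(0, 1; upper 0), mean -sqrt(2/pi)."""
        chain = pair_chain
        te = chain.events[0]
        second = te.rows[te.offsets[:-1] + 1]
        draws = []
        pred = chain.predicted()
        for _ in range(20):
            chain.sample_event_liabilities(0, pred, chain.Y - pred)
            draws.append(chain.Y[second, 0].copy())
        draws = np.concatenate(draws)  # 1e5 draws
        assert draws.mean() == pytest.approx(-HALF_NORMAL_MEAN, abs=0.01)
        # rejection-free dual route: scipy half-normal oracle
        ks = stats.kstest(draws, stats.truncnorm(-np.inf, 0).cdf)
        assert ks.pvalue > 1e-4

    def test_rank_order_invariant_after_sweep(self, tiny_study):
        chain = make_chain(tiny_study.model, tiny_study.data, tiny_study.pedigree, seed=5)
        pred = chain.predicted()
        chain.sample_event_liabilities(0, pred, chain.Y - pred)
        te = chain.events[0]
        for k in range(te.n_events):
            liab = chain.Y[te.event_rows(k), 0]
            assert liab[0] == 0.0
            assert np.all(np.diff(liab) < 0)


class TestThresholdLiabilities:
    def binary_chain(self, n=20000):
        model = rt.ModelSpec(
            traits=[rt.TraitSpec("t", "threshold", n_categories=2)],
            effects=[rt.EffectSpec("animal", "additive_genetic", 2, (0,))],
        )
        cats = np.tile([1.0, 2.0], n // 2)
        data = plain_data(n, 1, cats)
        return make_chain(model, data, founders_pedigree(2), seed=9), cats

    def test_binary_categories_half_normal(self):
        chain, cats = self.binary_chain()
        pred = chain.predicted()
        chain.sample_threshold_liabilities(0, pred, chain.Y - pred)
        hi = chain.Y[cats == 2, 0]
        lo = chain.Y[cats == 1, 0]
        assert hi.mean() == pytest.approx(HALF_NORMAL_MEAN, abs=0.02)
        assert np.all(hi > 0) and np.all(lo <= 0)
        ks = stats.kstest(lo, stats.truncnorm(-np.inf, 0).cdf)
        assert ks.pvalue > 1e-4

    def test_rethresholded_frequencies_match_probit(self):
        """Augment, re-simulate categories from the liability model, repeat:
        category frequencies converge to Phi differences."""
        chain, cats = self.binary_chain(n=10000)
        pred = chain.predicted()
        freqs = []
        for _ in range(30):
            chain.sample_threshold_liabilities(0, pred, chain.Y - pred)
            fresh = pred[:, 0] + chain.rng.standard_normal(chain.n_rows)
            freqs.append((fresh > 0).mean())
        assert np.mean(freqs) == pytest.approx(stats.norm.sf(0.0), abs=0.01)

    def test_multicategory_thresholds_stay_ordered(self):
        model = rt.ModelSpec(
            traits=[rt.TraitSpec("t", "threshold", n_categories=4)],
            effects=[rt.EffectSpec("animal", "additive_genetic", 2, (0,))],
        )
        rng = np.random.default_rng(4)
        cats = rng.integers(1, 5, size=2000).astype(float)
        chain = make_chain(model, plain_data(2000, 1, cats), founders_pedigree(2), seed=6)
        for _ in range(50):
            pred = chain.predicted()
            chain.sample_threshold_liabilities(0, pred, chain.Y - pred)
            thr = chain.thresholds[0]
            assert thr[1] == 0.0
            assert np.all(np.diff(thr) > 0)
            c = cats.astype(int)
            assert np.all(chain.Y[:, 0] > thr[c - 1]) and np.all(chain.Y[:, 0] <= thr[c])

    def test_category_outside_range_rejected(self):
        model = rt.ModelSpec(
            traits=[rt.TraitSpec("t", "threshold", n_categories=2)],
            effects=[rt.EffectSpec("animal", "additive_genetic", 2, (0,))],
        )
        with pytest.raises(rt.DataError, match="categories"):
            make_chain(model, plain_data(4, 1, [1.0, 2.0, 3.0, 1.0]), founders_pedigree(2))


class TestLocationEffects:
    def test_mean_full_conditional_is_conjugate_normal(self):
        """Flat prior, known residual variance: mean | y ~ N(ybar, sigma2/n)."""
        rng = np.random.default_rng(11)
        y = rng.normal(5.0, np.sqrt(2.0), size=200)
        model = continuous_model(3, with_mean=True)
        levels = np.zeros((200, 2), dtype=np.int64)
        levels[:, 0] = 1  # the mean applies to every row; no animal records
        data = rt.DataTable(
            levels=levels, values=y[:, None],
            event_ids=np.zeros((200, 1), dtype=np.int64),
            positions=np.zeros((200, 1), dtype=np.int64),
        )
        chain = make_chain(model, data, founders_pedigree(3), seed=12)
        chain.R = np.array([[2.0]])
        draws = np.empty(4000)
        for k in range(4000):
            E = chain.Y - chain.predicted()
            chain.sample_location_effects(E)
            draws[k] = chain.sol[0][0, 0]
        assert draws.mean() == pytest.approx(y.mean(), abs=0.01)
        assert draws.var() == pytest.approx(2.0 / 200, rel=0.1)

    def test_additive_prior_recovery(self):
        """No records: repeated sweeps sample a ~ MVN(0, G kron A)."""
        ped = rt.PedigreeTable(
            sire=np.array([0, 0, 1, 1, 0]), dam=np.array([0, 0, 2, 2, 0])
        )
        G0 = np.array([[1.0, 0.5], [0.5, 2.0]])
        model = continuous_model(5, n_traits=2)
        chain = make_chain(model, plain_data(1, 1, [[0.0, 0.0]]), ped, seed=13)
        chain.G = G0.copy()
        K = 10000
        samp = np.empty((K, 5, 2))
        for k in range(K):
            E = chain.Y - chain.predicted()
            chain.sample_location_effects(E)
            samp[k] = chain.a
        A = rt.build_a_tabular(ped)
        # variances, full-sib covariance, cross-trait covariance
        assert samp[:, 2, 0].var() == pytest.approx(G0[0, 0] * A[2, 2], abs=0.12)
        assert samp[:, 3, 1].var() == pytest.approx(G0[1, 1] * A[3, 3], abs=0.25)
        cov_sibs = np.cov(samp[:, 2, 0], samp[:, 3, 0])[0, 1]
        assert cov_sibs == pytest.approx(G0[0, 0] * A[2, 3], abs=0.1)
        cov_traits = np.cov(samp[:, 2, 0], samp[:, 2, 1])[0, 1]
        assert cov_traits == pytest.approx(G0[0, 1] * A[2, 2], abs=0.12)
        cov_unrel = np.cov(samp[:, 2, 0], samp[:, 4, 0])[0, 1]
        assert cov_unrel == pytest.approx(0.0, abs=0.1)

    def test_unobserved_systematic_level_is_skipped(self, tiny_study):
        model = rt.ModelSpec(
            traits=tiny_study.model.traits,
            effects=[
                rt.EffectSpec("mean", "systematic", 2, (0, 1)),  # level 2 never seen
                *tiny_study.model.effects[1:],
            ],
        )
        chain = make_chain(model, tiny_study.data, tiny_study.pedigree, seed=2)
        assert ("mean", 2) in chain.skipped_levels
        E = chain.Y - chain.predicted()
        chain.sample_location_effects(E)
        assert chain.sol[0][1, 0] == 0.0 and chain.sol[0][0, 0] != 0.0


class TestGeneticCovariance:
    def test_univariate_flat_prior_closed_form(self):
        """Flat prior: sigma2_a | a ~ q / chi2(N - 2), mean q/(N - 4)."""
        rng = np.random.default_rng(21)
        ped = random_pedigree(rng, 30)
        model = continuous_model(30)
        chain = make_chain(model, plain_data(1, 1, [0.0]), ped, seed=22)
        a0 = rng.normal(size=(30, 1))
        chain.sol[chain.additive_index][:] = a0
        q = float(a0[:, 0] @ (chain.ainv.matrix @ a0[:, 0]))
        draws = np.empty(20000)
        for k in range(20000):
            chain.sample_genetic_covariance()
            draws[k] = chain.G[0, 0]
        assert draws.mean() == pytest.approx(q / (30 - 4), rel=0.01)

    def test_zero_vector_with_proper_prior(self):
        """a = 0: the draw reduces to IW(S0, N + df0) exactly."""
        model = continuous_model(10)
        chain = make_chain(
            model, plain_data(1, 1, [0.0]), founders_pedigree(10), seed=23,
            g_prior=rt.IWPrior(df=6.0, scale=np.array([[1.0]])),
        )
        chain.sol[chain.additive_index][:] = 0.0
        draws = np.empty(20000)
        for k in range(20000):
            chain.sample_genetic_covariance()
            draws[k] = chain.G[0, 0]
        # d=1 inverted Wishart mean: S/(df - 2) with df = N + df0 = 16
        assert draws.mean() == pytest.approx(1.0 / 14.0, rel=0.02)

    def test_bivariate_iw_moment_oracle(self):
        rng = np.random.default_rng(24)
        S = np.array([[2.0, 0.6], [0.6, 1.5]])
        df = 12.0
        draws = np.zeros((20000, 2, 2))
        for k in range(draws.shape[0]):
            draws[k] = rt.sample_invwishart(rng, S, df)
        expect = stats.invwishart(df=df, scale=S).mean()
        np.testing.assert_allclose(expect, S / (df - 3), rtol=1e-12)
        np.testing.assert_allclose(draws.mean(axis=0), expect, rtol=0.05, atol=0.02)


class TestResidualCovariance:
    def bivariate_chain(self, n, rng):
        model = rt.ModelSpec(
            traits=[
                rt.TraitSpec("liab", "ranking"),
                rt.TraitSpec("y", "continuous"),
            ],
            effects=[rt.EffectSpec("animal", "additive_genetic", 2, (0, 1))],
        )
        data = rt.DataTable(
            levels=np.zeros((n, 1), dtype=np.int64),
            values=np.column_stack([np.full(n, np.nan), rng.normal(size=n)]),
            event_ids=np.zeros((n, 2), dtype=np.int64),
            positions=np.zeros((n, 2), dtype=np.int64),
        )
        return make_chain(model, data, founders_pedigree(2), seed=31)

    def test_constrained_update_recovers_correlation(self):
        """Known residual pairs with correlation -0.2: posterior matches the
        sample covariance of the pairs, with the liability variance fixed."""
        rng = np.random.default_rng(32)
        n = 100_000
        cov = -0.2 * np.sqrt(2.0)
        Rtrue = np.array([[1.0, cov], [cov, 2.0]])
        E = rng.standard_normal((n, 2)) @ np.linalg.cholesky(Rtrue).T
        chain = self.bivariate_chain(n, rng)
        corr = np.empty(200)
        for k in range(200):
            chain.sample_residual_covariance(E)
            assert chain.R[0, 0] == 1.0  # bit-exact constraint
            corr[k] = chain.R[0, 1] / np.sqrt(chain.R[0, 0] * chain.R[1, 1])
        sample_corr = np.corrcoef(E[:, 0], E[:, 1])[0, 1]
        assert corr.mean() == pytest.approx(sample_corr, abs=0.01)
        assert corr.mean() == pytest.approx(-0.2, abs=0.01)

    def test_single_ranking_trait_is_noop(self):
        model = rt.ModelSpec(
            traits=[rt.TraitSpec("liab", "ranking")],
            effects=[rt.EffectSpec("animal", "additive_genetic", 2, (0,))],
        )
        data = rt.DataTable(
            levels=np.zeros((4, 1), dtype=np.int64),
            values=np.full((4, 1), np.nan),
            event_ids=np.array([[1], [1], [2], [2]]),
            positions=np.array([[1], [2], [1], [2]]),
        )
        chain = make_chain(model, data, founders_pedigree(2))
        before = chain.R.copy()
        chain.sample_residual_covariance(chain.Y - chain.predicted())
        np.testing.assert_array_equal(chain.R, before)
        assert chain.R[0, 0] == 1.0

    def test_unconstrained_update_matches_crossproduct_scale(self):
        rng = np.random.default_rng(33)
        n = 50_000
        model = continuous_model(2, n_traits=2)
        E = rng.standard_normal((n, 2)) @ np.linalg.cholesky(
            np.array([[1.5, 0.4], [0.4, 0.8]])
        ).T
        chain = make_chain(model, plain_data(n, 1, np.zeros((n, 2))), founders_pedigree(2))
        draws = np.zeros((100, 2, 2))
        for k in range(100):
            chain.sample_residual_covariance(E)
            draws[k] = chain.R
        # flat prior: posterior mean ~ E'E/(n - 2t - 2)
        expect = (E.T @ E) / (n - 2 * 2 - 2)
        np.testing.assert_allclose(draws.mean(axis=0), expect, rtol=0.02, atol=0.01)


class TestAugmentMissing:
    def test_fully_observed_is_noop(self, tiny_study):
        chain = make_chain(tiny_study.model, tiny_study.data, tiny_study.pedigree)
        # every row of the study carries a rank and a continuous record
        assert not chain._patterns

    def test_independent_missing_draws_marginal(self):
        rng = np.random.default_rng(41)
        n = 5000
        model = continuous_model(2, n_traits=2)
        vals = np.column_stack([rng.normal(size=n), np.full(n, np.nan)])
        chain = make_chain(model, plain_data(n, 1, vals), founders_pedigree(2), seed=42)
        chain.R = np.array([[1.0, 0.0], [0.0, 2.0]])
        aug = []
        for _ in range(20):
            pred = chain.predicted()
            E = chain.Y - pred
            chain.augment_missing(pred, E)
            aug.append(chain.Y[:, 1].copy())
        aug = np.concatenate(aug)
        assert aug.mean() == pytest.approx(0.0, abs=0.02)
        assert aug.var() == pytest.approx(2.0, rel=0.03)

    def test_correlated_missing_matches_conditional_formula(self):
        rng = np.random.default_rng(43)
        n = 5000
        model = continuous_model(2, n_traits=2)
        y1 = rng.normal(size=n)
        vals = np.column_stack([y1, np.full(n, np.nan)])
        chain = make_chain(model, plain_data(n, 1, vals), founders_pedigree(2), seed=44)
        chain.R = np.array([[1.0, 0.6], [0.6, 2.0]])
        dev = []
        for _ in range(20):
            pred = chain.predicted()
            E = chain.Y - pred
            chain.augment_missing(pred, E)
            dev.append(chain.Y[:, 1] - 0.6 * y1)
        dev = np.concatenate(dev)
        assert dev.mean() == pytest.approx(0.0, abs=0.02)
        assert dev.var() == pytest.approx(2.0 - 0.36, rel=0.03)
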