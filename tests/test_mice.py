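"""Chained-equation MI: posterior draws, imputers, pooling."""

import numpy as np
import pytest
from scipy.stats import kstest, skew

import tvmiss as tv
from tvmiss.mice import (
    default_method_map,
    draw_posterior_params,
    impute_linear,
    impute_logistic,
    impute_pmm,
    rubin_combine,
)


def _linear_data(n=400, k=3, sigma=1.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, k - 1))])
    beta = np.arange(1.0, k + 1.0)[:k]
    y = X @ beta + rng.normal(0, sigma, n)
    return X, y, beta


class TestPosteriorDraws:
    def test_mean_of_drawn_variance_matches_inverse_chisq(self):
        X, y, _ = _linear_data(n=60, sigma=2.0, seed=1)
        rng = np.random.default_rng(2)
        draws = [draw_posterior_params(y, X, rng) for _ in range(4000)]
        s2_hat = draws[0].sigma2_hat
        dof = draws[0].n_obs - draws[0].k
        expected = s2_hat * dof / (dof - 2)  # mean of scaled inverse chi-squared
        got = np.mean([d.sigma2_star for d in draws])
        assert got == pytest.approx(expected, rel=0.05)
        betas = np.array([d.beta_star for d in draws])
        np.testing.assert_allclose(betas.mean(axis=0), draws[0].beta_hat, atol=0.05)

    def test_noiseless_data_gives_exact_draws(self):
        X, y, beta = _linear_data(sigma=0.0, seed=3)
        y = X @ beta  # exactly linear
        draw = draw_posterior_params(y, X, np.random.default_rng(4))
        assert draw.sigma2_star == 0.0
        np.testing.assert_allclose(draw.beta_star, beta, atol=1e-8)

    def test_collinear_columns_are_dropped_with_warning(self):
        X, y, _ = _linear_data(seed=5)
        X_bad = np.column_stack([X, X[:, 1]])  # duplicate column
        with pytest.warns(RuntimeWarning, match="collinear"):
            draw = draw_posterior_params(y, X_bad, np.random.default_rng(6))
        assert draw.kept.size == X.shape[1]


class TestImputers:
    def test_linear_arithmetic_and_determinism(self):
        draw = draw_posterior_params(*_linear_data(sigma=0.0, seed=7)[1::-1],
                                     np.random.default_rng(8))
        # hand-built draw: beta*=(1,2), sigma2*=0 -> x=(1,3) imputes 7 exactly
        draw.beta_star = np.array([1.0, 2.0])
        draw.sigma2_star = 0.0
        draw.kept = np.arange(2)
        out = impute_linear(draw, np.array([[1.0, 3.0]]), np.random.default_rng(9))
        assert out[0] == pytest.approx(7.0)

    def test_linear_imputations_match_true_distribution(self):
        """Under a correctly specified normal model the imputed values are
        draws from the right conditional law (KS test not rejected)."""
        rng = np.random.default_rng(10)
        n = 4000
        x = rng.normal(size=n)
        y = 1.0 + 2.0 * x + rng.normal(0, 1.5, n)
        miss = rng.random(n) < 0.3  # MCAR
        X = np.column_stack([np.ones(n), x])
        draw = draw_posterior_params(y[~miss], X[~miss], rng)
        imp = impute_linear(draw, X[miss], rng)
        z = (imp - (1.0 + 2.0 * x[miss])) / 1.5  # standardized under truth
        assert kstest(z, "norm").pvalue > 0.01

    def test_pmm_nearest_neighbor_and_closure(self):
        rng = np.random.default_rng(11)
        X, y, _ = _linear_data(n=200, seed=12)
        draw = draw_posterior_params(y, X, rng)
        X_miss = X[:20] + 0.01
        imp = impute_pmm(draw, X, y, X_miss, q=5, rng=rng)
        assert np.all(np.isin(imp, y))  # closure: imputed subset of observed
        # q=1 with distinct predictions is the deterministic nearest donor
        draw.beta_star = draw.beta_hat  # type-1 == type-2 when equal
        imp1 = impute_pmm(draw, X, y, X_miss, q=1, rng=rng)
        pred_obs = X @ draw.beta_hat
        pred_miss = X_miss @ draw.beta_star
        expected = y[np.abs(pred_obs[None] - pred_miss[:, None]).argmin(axis=1)]
        np.testing.assert_allclose(imp1, expected)

    def test_pmm_ties_are_all_eligible(self):
        rng = np.random.default_rng(13)
        draw = draw_posterior_params(*_linear_data(seed=14)[1::-1], rng)
        draw.beta_star = np.array([0.0, 1.0])
        draw.beta_hat = np.array([0.0, 1.0])
        draw.kept = np.arange(2)
        # four donors at identical distance; all must be sampled eventually
        X_obs = np.array([[1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [1.0, 1.0]])
        y_obs = np.array([10.0, 20.0, 30.0, 40.0])
        X_miss = np.array([[1.0, 0.0]])
        seen = {impute_pmm(draw, X_obs, y_obs, X_miss, q=1,
                           rng=np.random.default_rng(s))[0] for s in range(200)}
        assert seen == {10.0, 20.0, 30.0, 40.0}

    def test_pmm_preserves_skewness_unlike_linear(self):
        rng = np.random.default_rng(15)
        n = 6000
        x = rng.normal(size=n)
        y = x + (rng.lognormal(0, 1.0, n) - np.exp(0.5))
        miss = rng.random(n) < 0.35
        X = np.column_stack([np.ones(n), x])
        draw = draw_posterior_params(y[~miss], X[~miss], rng)
        lin = impute_linear(draw, X[miss], rng)
        pmm = impute_pmm(draw, X[~miss], y[~miss], X[miss], q=5, rng=rng)
        true_skew = skew(y[miss])
        assert abs(skew(pmm) - true_skew) < abs(skew(lin) - true_skew)
        assert skew(pmm) > 1.0  # right-skew carried through

    def test_logistic_prevalence_recovery(self):
        rng = np.random.default_rng(16)
        n = 30_000
        b = (rng.random(n) < 0.06).astype(float)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        miss = rng.random(n) < 0.3
        imp = impute_logistic(b[~miss], X[~miss], X[miss], rng)
        se = np.sqrt(0.06 * 0.94 / miss.sum())
        assert abs(imp.mean() - 0.06) < 4 * se
        assert set(np.unique(imp)) <= {0.0, 1.0}


class TestMiceRun:
    def test_no_missing_cells_returns_identical_copies(self, small_panel):
        stack = tv.mice_run(small_panel, M=3, seed=17)
        assert stack.M == 3
        for p in stack.panels:
            np.testing.assert_array_equal(p.x, small_panel.x)
            np.testing.assert_array_equal(p.y, small_panel.y)

    def test_reproducible_and_nonimputed_cells_fixed(self, coeffs):
        spec = tv.ScenarioSpec(pattern="mixed", level="high", n=400,
                               n_reps=2, m_imputations=2)
        panel = tv.generate_complete_panel(spec, coeffs, seed=18)
        blanked = tv.impose_missingness(panel, spec, coeffs, seed=19)
        s1 = tv.mice_run(blanked, M=3, n_iter=3, seed=20)
        s2 = tv.mice_run(blanked, M=3, n_iter=3, seed=20)
        for a, b in zip(s1.panels, s2.panels):
            np.testing.assert_array_equal(a.x, b.x)  # bit-identical rerun
            np.testing.assert_array_equal(a.y, b.y)
        obs = blanked.r_y == 1
        for p in s1.panels:
            np.testing.assert_array_equal(p.y[obs], blanked.y[obs])
            assert p.is_complete()

    def test_method_map_validation(self, small_panel):
        with pytest.raises(ValueError, match="unknown columns"):
            tv.mice_run(small_panel, M=2, method_map={"z9": "linear"}, seed=0)
        with pytest.raises(ValueError, match="M must be"):
            tv.mice_run(small_panel, M=1, seed=0)

    def test_default_method_map_targets_incomplete_columns(self, coeffs):
        spec = tv.ScenarioSpec(pattern="nm_outcome", level="high", n=300,
                               n_reps=2, m_imputations=2)
        panel = tv.generate_complete_panel(spec, coeffs, seed=21)
        blanked = tv.impose_missingness(panel, spec, coeffs, seed=22)
        mm = default_method_map(blanked, pmm_for_outcome=True)
        assert all(v == "pmm" for k, v in mm.items() if k.startswith("y"))
        assert all(v == "linear" for k, v in mm.items() if k.startswith("x"))


class TestRubin:
    def test_printed_arithmetic_example(self):
        pooled = rubin_combine([(1.0, 0.1), (2.0, 0.1), (3.0, 0.1)])
        assert pooled.theta == pytest.approx(2.0)
        assert pooled.W == pytest.approx(0.1)
        assert pooled.B == pytest.approx(1.0)
        assert pooled.V == pytest.approx(0.1 + (1 + 1 / 3) * 1.0)

    def test_identical_estimates_have_no_between_variance(self):
        pooled = rubin_combine([(0.5, 0.2)] * 4)
        assert pooled.B == 0.0 and pooled.V == pooled.W
        assert np.isinf(pooled.df)

    def test_total_variance_dominates_within(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            est = [(rng.normal(), rng.random()) for _ in range(5)]
            p = rubin_combine(est)
            assert p.V >= p.W - 1e-12 and p.B >= 0
            assert p.V == pytest.approx(p.W + (1 + 1 / p.M) * p.B)

    def test_m_below_two_is_rejected(self):
        with pytest.raises(ValueError):
            rubin_combine([(1.0, 0.1)])

    def test_proper_mi_interval_coverage(self):
        """95% Rubin intervals for a normal mean under MCAR cover in [0.92, 0.98]."""
        rng = np.random.default_rng(24)
        n, M, reps = 150, 20, 700
        hits = 0
        for _ in range(reps):
            y = rng.normal(0.0, 1.0, n)
            miss = rng.random(n) < 0.4
            ests = []
            X = np.ones((n, 1))
            draw_src = y[~miss]
            for _ in range(M):
                draw = draw_posterior_params(draw_src, X[~miss], rng)
                y_imp = y.copy()
                y_imp[miss] = impute_linear(draw, X[miss], rng)
                ests.append((y_imp.mean(), y_imp.var(ddof=1) / n))
            lo, hi = rubin_combine(ests).ci()
            hits += lo <= 0.0 <= hi
        assert 0.92 <= hits / reps <= 0.98
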