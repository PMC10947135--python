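"""Treatment/missingness models, stabilized weights, monotonization."""

from dataclasses import replace

import numpy as np
import pytest
import statsmodels.api as sm

import tvmiss as tv
from tvmiss._glm import DegenerateResponseError, fit_logit
from tvmiss.config import make_fixture
from tvmiss.weights import ConstantModel, PooledLogit, WeightVector


@pytest.fixture(scope="module")
def fitted(big_panel):
    models = tv.fit_treatment_models(big_panel)
    sw = tv.stabilized_treatment_weights(big_panel, models)
    return models, sw


class TestLogisticBackend:
    def test_irls_matches_statsmodels(self, small_panel):
        rows = []
        for t in range(1, 5):
            rows.append(np.column_stack([
                small_panel.a[:, t], small_panel.a[:, t - 1],
                small_panel.x[:, t], small_panel.y[:, t - 1],
                small_panel.b_cont,
            ]))
        data = np.vstack(rows)
        X = sm.add_constant(data[:, 1:])
        beta, cov = fit_logit(X, data[:, 0])
        ref = sm.GLM(data[:, 0], X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(beta, ref.params, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(np.sqrt(np.diag(cov)), ref.bse, rtol=1e-4)

    def test_degenerate_response_raises(self):
        X = np.column_stack([np.ones(50), np.arange(50.0)])
        with pytest.raises(DegenerateResponseError):
            fit_logit(X, np.ones(50))


class TestTreatmentModels:
    def test_denominator_recovers_generating_slopes(self, coeffs, fitted):
        (num, den), _ = fitted
        truth = {"a_lag": coeffs.a_on_a_lag, "x_cur": coeffs.a_on_x,
                 "y_lag": coeffs.a_on_y_lag,
                 "b_cont": coeffs.a_on_b_std / coeffs.b_cont_sd}
        se = np.sqrt(np.diag(den.cov))
        for name, true_val in truth.items():
            j = den.columns.index(name)
            assert abs(den.beta[j] - true_val) < 3.5 * se[j], name

    def test_no_confounding_gives_unit_weights(self, coeffs):
        flat = replace(coeffs, a_on_x=0.0, a_on_y_lag=0.0, a_on_b_std=0.0,
                       a_on_b_bin=0.0)
        panel = tv.generate_complete_panel(50_000, flat, seed=14)
        models = tv.fit_treatment_models(panel)
        sw = tv.stabilized_treatment_weights(panel, models)
        final = sw.final()
        assert abs(final.mean() - 1.0) < 0.01
        assert final.std() < 0.05

    def test_constant_treatment_is_a_positivity_error(self, coeffs):
        panel = tv.generate_complete_panel(300, coeffs, seed=15)
        panel.a[:, 2] = 1
        with pytest.raises(tv.weights.PositivityViolation):
            tv.fit_treatment_models(panel)

    def test_missing_covariate_is_named(self, coeffs):
        panel = tv.generate_complete_panel(300, coeffs, seed=16)
        panel.x[5, 2] = np.nan
        with pytest.raises(ValueError, match="visit 2"):
            tv.fit_treatment_models(panel)


class TestStabilizedWeights:
    def test_mean_close_to_one_at_every_visit(self, fitted):
        _, sw = fitted
        cum = sw.cumulative
        n = cum.shape[0]
        for t in range(1, 5):
            mc_se = cum[:, t].std() / np.sqrt(n)
            assert abs(cum[:, t].mean() - 1.0) < 3 * mc_se + 1e-3

    def test_weighted_covariate_balance(self, coeffs, big_panel, fitted):
        """In the SW pseudo-population treatment no longer loads on the
        time-varying confounder given (A_lag, B): the weighted pooled-logistic
        coefficient on X_t collapses from ~0.5 to ~0."""
        _, sw = fitted
        cum = sw.cumulative
        bs = coeffs.b_std(big_panel.b_cont)
        for t in range(1, 5):
            a = big_panel.a[:, t].astype(float)
            X = sm.add_constant(np.column_stack([
                big_panel.x[:, t], big_panel.a[:, t - 1], bs, big_panel.b_bin]))
            fit = sm.GLM(a, X, family=sm.families.Binomial(),
                         var_weights=cum[:, t]).fit()
            assert abs(fit.params[1]) < 0.03  # generating value is 0.5

    def test_single_visit_ratio_arithmetic(self):
        num = np.array([[1.0, 0.5]])
        den = np.array([[1.0, 0.25]])
        wv = WeightVector("treatment", num, den)
        assert wv.ratio[0, 1] == pytest.approx(2.0)
        assert wv.final()[0] == pytest.approx(2.0)

    def test_total_weight_arithmetic_and_identity(self):
        sw = WeightVector("treatment", np.array([[1.0, 0.75]]), np.array([[1.0, 0.5]]))
        mw_y = WeightVector("missingness", np.array([[1.0, 0.9]]), np.array([[1.0, 0.45]]))
        mw_x = WeightVector("missingness", np.array([[1.0, 0.6]]), np.array([[1.0, 0.5]]))
        tw = tv.total_weights(sw, mw_y, mw_x)
        assert tw.final()[0] == pytest.approx(1.5 * 2.0 * 1.2)
        ones = WeightVector("missingness", np.ones((1, 2)), np.ones((1, 2)))
        np.testing.assert_allclose(tv.total_weights(sw, ones).final(), sw.final())

    def test_total_weights_rejects_support_mismatch(self):
        a = WeightVector("treatment", np.ones((2, 5)), np.ones((2, 5)))
        b = WeightVector("missingness", np.ones((3, 5)), np.ones((3, 5)))
        with pytest.raises(ValueError, match="support"):
            tv.total_weights(a, b)


class TestMonotonization:
    def test_intermittent_pattern_censored_from_first_gap(self):
        panel = make_fixture("table1_patient1")
        cens = tv.censor_after_first_missing(panel)
        assert np.all(cens.r_x[0, 1:] == 0) and np.all(cens.r_y[0, 1:] == 0)
        assert cens.r_x[0, 0] == 1 and cens.r_y[0, 0] == 1

    def test_complete_and_dropout_rows_unchanged(self):
        complete = make_fixture("complete")
        np.testing.assert_array_equal(
            tv.censor_after_first_missing(complete).r_x, complete.r_x)
        dropout = make_fixture("dropout")
        cens = tv.censor_after_first_missing(dropout)
        np.testing.assert_array_equal(cens.r_x, dropout.r_x)
        np.testing.assert_array_equal(cens.r_y, dropout.r_y)

    def test_output_always_monotone(self, coeffs):
        spec = tv.ScenarioSpec(pattern="mixed", level="high", n=3000,
                               n_reps=2, m_imputations=2)
        panel = tv.generate_complete_panel(spec, coeffs, seed=17)
        blanked = tv.impose_missingness(panel, spec, coeffs, seed=18)
        assert tv.censor_after_first_missing(blanked).is_monotone()


class TestMissingnessModels:
    def test_mcar_hazard_matches_rate(self, coeffs):
        rng = np.random.default_rng(19)
        panel = tv.generate_complete_panel(40_000, coeffs, seed=19)
        blank = rng.random((panel.n, 4)) < 0.2
        panel.r_y[:, 1:][blank] = 0
        panel.y[:, 1:][blank] = np.nan
        cens = tv.censor_after_first_missing(panel)
        num, den = tv.fit_missingness_models(cens)
        # with MCAR blanking the per-visit continuation hazard is 0.8 and
        # no history variable should carry signal
        from tvmiss.weights import _stack_rows
        obs = cens.observed()
        at_risk = np.ones((cens.n, cens.T), dtype=bool)
        at_risk[:, 1:] = obs[:, :-1]
        _, _, _, _, den_X, den_cols = _stack_rows(cens, at_risk, True)
        assert den.predict(den_X).mean() == pytest.approx(0.8, abs=0.01)
        se = np.sqrt(np.diag(den.cov))
        for name in ("a_lag", "x_lag", "y_lag"):
            j = den.columns.index(name)
            assert abs(den.beta[j]) < 4 * se[j]

    def test_at_risk_construction_drops_censored_rows(self, coeffs):
        panel = tv.generate_complete_panel(2000, coeffs, seed=20)
        spec = tv.ScenarioSpec(pattern="monotone", level="high", n=2000,
                               n_reps=2, m_imputations=2)
        blanked = tv.impose_missingness(panel, spec, coeffs, seed=21)
        cens = tv.censor_after_first_missing(blanked)
        num, den = tv.fit_missingness_models(cens)
        obs = cens.observed()
        expected_rows = int(obs[:, :-1].sum())  # at risk = observed at t-1
        assert num.n_rows == expected_rows

    def test_all_observed_collapses_to_constant_model(self, coeffs):
        panel = tv.generate_complete_panel(500, coeffs, seed=22)
        num, den = tv.fit_missingness_models(panel)
        assert isinstance(num, ConstantModel) and isinstance(den, ConstantModel)
        mw = tv.stabilized_missingness_weights(panel, (num, den))
        np.testing.assert_allclose(mw.final(), 1.0)

    def test_generating_slopes_recovered(self, coeffs):
        spec = tv.ScenarioSpec(pattern="monotone", level="high", n=100_000,
                               n_reps=2, m_imputations=2)
        panel = tv.generate_complete_panel(spec, coeffs, seed=23)
        blanked = tv.impose_missingness(panel, spec, coeffs, seed=24)
        cens = tv.censor_after_first_missing(blanked)
        num, den = tv.fit_missingness_models(cens)
        # hazard of *remaining observed*: slopes are minus the drop-out slopes
        truth = {"a_lag": -coeffs.m_on_a_lag, "x_lag": -coeffs.m_on_x_lag,
                 "y_lag": -coeffs.m_on_y_lag}
        se = np.sqrt(np.diag(den.cov))
        for name, val in truth.items():
            j = den.columns.index(name)
            assert abs(den.beta[j] - val) < 3.5 * se[j], name
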