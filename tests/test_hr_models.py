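"""OLS model fits, AICc comparison, prediction and cohort tallies."""

import math

import numpy as np
import pytest

from respcoupling import (
    SignalTrace,
    SimulationParams,
    aicc,
    compare_models,
    fit_cmodel1,
    fit_cmodel2,
    generate_rsp,
    predict_hrm,
    simulate_hr,
    summarize_models,
    time_derivative,
)
from respcoupling.errors import ConfigError, PairingError, RankError
from respcoupling.hr_models import CMODEL1, CMODEL2, ModelComparison

FS = 100.0


def _trace(values, fs=FS, label="x"):
    return SignalTrace(np.asarray(values, float), fs, label)


class TestFits:
    def test_cmodel1_exact_linear_relation(self, rng):
        rsp = _trace(rng.standard_normal(200))
        hr = _trace(0.5 + 2.0 * rsp.samples)
        fit = fit_cmodel1(hr, rsp)
        assert fit.b0 == pytest.approx(0.5, abs=1e-10)
        assert fit.b1 == pytest.approx(2.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.k == 3 and fit.b2 is None

    def test_cmodel1_null_relation(self, rng):
        rsp = _trace(rng.standard_normal(10_000))
        hr = _trace(rng.standard_normal(10_000))
        assert fit_cmodel1(hr, rsp).r2 < 0.01

    def test_standardized_slope_equals_pearson(self, rng):
        x = rng.standard_normal(2000)
        y = 0.6 * x + rng.standard_normal(2000)
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        fit = fit_cmodel1(_trace(zy), _trace(zx))
        assert fit.b1 == pytest.approx(np.corrcoef(zx, zy)[0, 1], abs=1e-9)

    def test_cmodel2_exact_recovery(self, rng):
        rsp = _trace(rng.standard_normal(300))
        drsp = _trace(rng.standard_normal(300))
        hr = _trace(2.0 + 3.0 * rsp.samples - 0.5 * drsp.samples)
        fit = fit_cmodel2(hr, rsp, drsp)
        assert fit.b0 == pytest.approx(2.0, abs=1e-9)
        assert fit.b1 == pytest.approx(3.0, abs=1e-9)
        assert fit.b2 == pytest.approx(-0.5, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.k == 4

    def test_residuals_orthogonal_to_regressors(self, rng):
        rsp = _trace(rng.standard_normal(500))
        drsp = _trace(rng.standard_normal(500))
        hr = _trace(rng.standard_normal(500))
        fit = fit_cmodel2(hr, rsp, drsp)
        resid = hr.samples - (
            fit.b0 + fit.b1 * rsp.samples + fit.b2 * drsp.samples
        )
        for reg in (np.ones(500), rsp.samples, drsp.samples):
            assert abs(resid @ reg) < 1e-8 * np.linalg.norm(reg) * np.linalg.norm(
                hr.samples
            )

    def test_brute_force_normal_equations_oracle(self, rng):
        n = 50
        rsp = _trace(rng.standard_normal(n))
        drsp = _trace(rng.standard_normal(n))
        hr = _trace(rng.standard_normal(n))
        design = np.column_stack([np.ones(n), rsp.samples, drsp.samples])
        expected = np.linalg.solve(design.T @ design, design.T @ hr.samples)
        fit = fit_cmodel2(hr, rsp, drsp)
        np.testing.assert_allclose([fit.b0, fit.b1, fit.b2], expected, atol=1e-9)

    def test_statsmodels_cross_check(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        n = 400
        rsp = _trace(rng.standard_normal(n))
        drsp = _trace(rng.standard_normal(n))
        hr = _trace(
            1.0 + 0.8 * rsp.samples - 0.3 * drsp.samples + 0.2 * rng.standard_normal(n)
        )
        fit = fit_cmodel2(hr, rsp, drsp)
        design = sm.add_constant(np.column_stack([rsp.samples, drsp.samples]))
        ref = sm.OLS(hr.samples, design).fit()
        np.testing.assert_allclose(
            [fit.b0, fit.b1, fit.b2], ref.params, rtol=1e-8
        )
        assert fit.rss == pytest.approx(ref.ssr, rel=1e-8)
        assert fit.r2 == pytest.approx(ref.rsquared, rel=1e-8)

    def test_nesting_r2(self, rng):
        for _ in range(5):
            rsp = _trace(rng.standard_normal(200))
            drsp = _trace(rng.standard_normal(200))
            hr = _trace(rng.standard_normal(200))
            assert fit_cmodel2(hr, rsp, drsp).r2 >= fit_cmodel1(hr, rsp).r2

    def test_constant_regressor_rejected(self):
        rsp = _trace(np.full(50, 2.0))
        hr = _trace(np.arange(50.0))
        with pytest.raises(RankError):
            fit_cmodel1(hr, rsp)

    def test_collinear_derivative_rejected(self, rng):
        rsp = _trace(rng.standard_normal(50))
        drsp = _trace(2.0 * rsp.samples)
        hr = _trace(rng.standard_normal(50))
        with pytest.raises(RankError):
            fit_cmodel2(hr, rsp, drsp)


class TestAicc:
    def test_direct_formula_value(self):
        # 100*ln(25/100) + 2*3 + 2*3*4/(100-3-1)
        assert aicc(25.0, 100, 3) == pytest.approx(-132.37943611198905, abs=1e-10)

    def test_penalty_monotone_in_k(self):
        assert aicc(25.0, 100, 4) > aicc(25.0, 100, 3)

    def test_correction_vanishes_for_large_n(self):
        n = 1_000_000
        assert aicc(0.25 * n, n, 3) / n == pytest.approx(math.log(0.25), abs=1e-4)

    def test_preconditions(self):
        with pytest.raises(ConfigError):
            aicc(25.0, 4, 3)
        with pytest.raises(ConfigError):
            aicc(0.0, 100, 3)


class TestCompareModels:
    @staticmethod
    def _fits(rss1, rss2, n=100):
        from respcoupling.hr_models import ModelFit

        return (
            ModelFit(CMODEL1, 0.0, 1.0, None, rss1, 0.5, n, 3),
            ModelFit(CMODEL2, 0.0, 1.0, -0.1, rss2, 0.6, n, 4),
        )

    def test_smaller_rss_wins(self):
        fit1, fit2 = self._fits(100.0, 10.0)
        assert compare_models(fit1, fit2, "s").winner == CMODEL2

    def test_tie_goes_to_fewer_parameters(self):
        fit1, fit2 = self._fits(50.0, 50.0)
        assert compare_models(fit1, fit2, "s").winner == CMODEL1

    def test_decision_invariant_to_common_rss_scaling(self):
        # scaling both RSS by c shifts both AICc by n*ln(c): winner unchanged
        for rss1, rss2 in [(100.0, 10.0), (40.0, 39.9), (50.0, 50.0)]:
            base = compare_models(*self._fits(rss1, rss2), "s").winner
            scaled = compare_models(*self._fits(7.3 * rss1, 7.3 * rss2), "s").winner
            assert base == scaled

    def test_mismatched_n_rejected(self):
        from respcoupling.hr_models import ModelFit

        fit1 = ModelFit(CMODEL1, 0.0, 1.0, None, 10.0, 0.5, 100, 3)
        fit2 = ModelFit(CMODEL2, 0.0, 1.0, -0.1, 10.0, 0.6, 99, 4)
        with pytest.raises(PairingError):
            compare_models(fit1, fit2)

    def test_delta_sign_convention(self):
        comp = compare_models(*self._fits(100.0, 10.0), "s")
        assert comp.delta_aicc == pytest.approx(comp.aicc1 - comp.aicc2)
        assert comp.delta_aicc > 0


class TestPredict:
    def test_identity_coefficients_reproduce_rsp(self, rng):
        from respcoupling.hr_models import ModelFit

        rsp = _trace(rng.standard_normal(100))
        fit = ModelFit(CMODEL1, 0.0, 1.0, None, 1.0, 1.0, 100, 3)
        np.testing.assert_array_equal(predict_hrm(fit, rsp).samples, rsp.samples)

    def test_perfect_fit_correlates_exactly(self, rng):
        rsp = _trace(rng.standard_normal(200))
        drsp = _trace(rng.standard_normal(200))
        hr = _trace(1.0 + 2.0 * rsp.samples - 0.7 * drsp.samples)
        fit = fit_cmodel2(hr, rsp, drsp)
        hrm = predict_hrm(fit, rsp, drsp)
        assert np.corrcoef(hrm.samples, hr.samples)[0, 1] == pytest.approx(
            1.0, abs=1e-9
        )

    def test_arity_mismatch_rejected(self, rng):
        rsp = _trace(rng.standard_normal(100))
        drsp = _trace(rng.standard_normal(100))
        hr = _trace(rng.standard_normal(100))
        fit1 = fit_cmodel1(hr, rsp)
        fit2 = fit_cmodel2(hr, rsp, drsp)
        with pytest.raises(ConfigError):
            predict_hrm(fit1, rsp, drsp)
        with pytest.raises(ConfigError):
            predict_hrm(fit2, rsp)

    def test_model2_prediction_steepens_hr_regression(self):
        # on simulator output, regressing HR on the model-2 prediction
        # gives a steeper positive slope than regressing HR on RSP alone
        params = SimulationParams(
            duration=60.0, fs=FS, delay_ms=850.0, gain2=-0.4, noise_sd=0.05, seed=3
        )
        rsp = generate_rsp(params)
        _, hr = simulate_hr(rsp, params)
        drsp = time_derivative(rsp)
        fit2 = fit_cmodel2(hr, rsp, drsp)
        hrm = predict_hrm(fit2, rsp, drsp)

        def slope(y, x):
            return np.polyfit(x, y, 1)[0]

        s_hrm = slope(hr.samples, hrm.samples)
        s_rsp = slope(hr.samples, rsp.samples)
        assert s_hrm > 0
        assert s_hrm > s_rsp


class TestSimulatorRoundTrip:
    def test_noise_free_gain_recovery(self):
        params = SimulationParams(
            duration=60.0,
            fs=FS,
            delay_ms=850.0,
            gain1=1.0,
            gain2=-0.4,
            gain3=1.5,
            noise_sd=0.0,
        )
        rsp = generate_rsp(params)
        delayed, advanced = simulate_hr(rsp, params)
        fit = fit_cmodel2(advanced, delayed, time_derivative(delayed))
        assert fit.b1 == pytest.approx(params.gain3 * params.gain1, abs=1e-6)
        assert fit.b2 == pytest.approx(params.gain3 * params.gain2, abs=1e-6)
        assert fit.r2 > 1 - 1e-9

    def test_b2_recovery_under_noise(self):
        # median absolute error of b2 across seeded noisy subjects
        errors = []
        for seed in range(20):
            params = SimulationParams(
                duration=30.0,
                fs=FS,
                breath_rate=0.2 + 0.005 * seed,
                delay_ms=600.0,
                gain2=-0.4,
                noise_sd=0.1,
                seed=seed,
            )
            rsp = generate_rsp(params)
            delayed, advanced = simulate_hr(rsp, params)
            fit = fit_cmodel2(advanced, delayed, time_derivative(delayed))
            errors.append(abs(fit.b2 - params.gain3 * params.gain2))
        assert np.median(errors) < 0.05


class TestSummarizeModels:
    @staticmethod
    def _fit2(b1, b2, n=100):
        from respcoupling.hr_models import ModelFit

        return ModelFit(CMODEL2, 0.0, b1, b2, 10.0, 0.9, n, 4)

    def test_counts(self):
        comparisons = [
            ModelComparison("a", -10.0, -20.0, CMODEL2),
            ModelComparison("b", -10.0, -5.0, CMODEL1),
            ModelComparison("c", -10.0, -30.0, CMODEL2),
        ]
        fits = [self._fit2(1.0, -1.0), self._fit2(-1.0, -1.0), self._fit2(2.0, 1.0)]
        summary = summarize_models(comparisons, fits)
        assert summary.n_subjects == 3
        assert summary.n_cmodel2_wins == 2
        assert summary.n_b1_positive == 2
        assert summary.n_b2_negative == 2

    def test_empty_or_mismatched_rejected(self):
        with pytest.raises(PairingError):
            summarize_models([], [])
        with pytest.raises(PairingError):
            summarize_models(
                [ModelComparison("a", -10.0, -20.0, CMODEL2)],
                [],
            )
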