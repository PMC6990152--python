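"""Eyring-plot transforms and Eyring/Q10 temperature-model fitting."""

import math
import warnings

import numpy as np
import pytest
from scipy import optimize, stats

import hergtemp as ht
from hergtemp.constants import CONSTANTS
from hergtemp.temperature import (EyringPlotSeries, RATE_COLUMNS,
                                  ge_log_a_over_t, q10_log_a_over_t,
                                  series_from_ge_coefficients,
                                  to_eyring_plot)

TEMPS_K = np.array([ht.celsius_to_kelvin(t) for t in (25, 27, 30, 33, 37)])


def q10_series(q10, alpha, beta, temps=TEMPS_K, tref=298.15):
    """Series generated exactly from a per-rate Q10 law."""
    mean = np.empty((len(temps), 8))
    for rate, (ia, ib) in RATE_COLUMNS.items():
        i = rate - 1
        A = alpha[i] * q10[i] ** ((temps - tref) / 10.0)
        mean[:, ia] = np.log(A / temps)
        mean[:, ib] = beta[i]
    return EyringPlotSeries(temps, mean, np.zeros_like(mean))


class TestToEyringPlot:
    def test_prefactor_equal_to_temperature_gives_zero(self):
        samples = []
        for T in (300.0, 310.0):
            phi = np.zeros((1, 9))
            phi[:, [1, 3, 5, 7]] = math.log(T)
            phi[:, [2, 4, 6, 8]] = math.log(0.05)
            samples.append(phi)
        series = to_eyring_plot([300.0, 310.0], samples)
        np.testing.assert_allclose(series.mean[:, [0, 2, 4, 6]], 0.0,
                                   atol=1e-14)

    def test_matches_hand_transformation_on_toy_samples(self):
        phi = np.log(np.array([[1.0, 2e-4, 0.07, 3e-5, 0.05, 0.09, 0.009,
                                5e-3, 0.03],
                               [1.0, 3e-4, 0.06, 4e-5, 0.06, 0.08, 0.010,
                                6e-3, 0.04],
                               [1.0, 2.5e-4, 0.08, 3.5e-5, 0.04, 0.07,
                                0.008, 4e-3, 0.02]]))
        T = 300.0
        series = to_eyring_plot([T, 310.0], [phi, phi])
        # A-type: mean/SD of ln(p/T); B-type: mean/SD of p
        lnA = phi[:, 1] - math.log(T)
        assert series.mean[0, 0] == pytest.approx(lnA.mean(), rel=1e-12)
        assert series.sd[0, 0] == pytest.approx(lnA.std(ddof=1), rel=1e-12)
        b = np.exp(phi[:, 2])
        assert series.mean[0, 1] == pytest.approx(b.mean(), rel=1e-12)
        assert series.sd[0, 1] == pytest.approx(b.std(ddof=1), rel=1e-12)

    def test_constant_samples_have_zero_sd(self):
        phi = np.tile(np.log(np.full(9, 0.01)), (4, 1))
        series = to_eyring_plot([298.15, 310.15], [phi, phi])
        np.testing.assert_array_equal(series.sd, 0.0)

    def test_needs_two_temperatures(self):
        with pytest.raises(ValueError):
            to_eyring_plot([300.0], [np.zeros((2, 9))])


class TestGeneralizedEyringFit:
    def test_exact_recovery_from_noiseless_lines(self, temp_truth):
        series = series_from_ge_coefficients(
            temp_truth.a_ge, temp_truth.b_ge, temp_truth.c_ge,
            temp_truth.d_ge, TEMPS_K)
        fit = ht.fit_generalized_eyring(series)
        np.testing.assert_allclose(fit.a_ge, temp_truth.a_ge, rtol=1e-10)
        np.testing.assert_allclose(fit.b_ge, temp_truth.b_ge, rtol=1e-10)
        np.testing.assert_allclose(fit.c_ge, temp_truth.c_ge, rtol=1e-10)
        np.testing.assert_allclose(fit.d_ge, temp_truth.d_ge, rtol=1e-10,
                                   atol=1e-12)

    def test_two_points_interpolate(self, temp_truth):
        series = series_from_ge_coefficients(
            temp_truth.a_ge, temp_truth.b_ge, temp_truth.c_ge,
            temp_truth.d_ge, TEMPS_K[:2])
        fit = ht.fit_generalized_eyring(series)
        np.testing.assert_allclose(fit.b_ge, temp_truth.b_ge, rtol=1e-9)

    def test_noisy_fit_matches_normal_equations_oracle(self, temp_truth):
        rng = np.random.default_rng(6)
        series = series_from_ge_coefficients(
            temp_truth.a_ge, temp_truth.b_ge, temp_truth.c_ge,
            temp_truth.d_ge, TEMPS_K)
        noisy = EyringPlotSeries(
            TEMPS_K, series.mean + rng.normal(0, 0.05, series.mean.shape),
            np.abs(rng.normal(0.1, 0.02, series.mean.shape)))
        fit = ht.fit_generalized_eyring(noisy)
        x = 1.0 / TEMPS_K
        X = np.vstack([x, np.ones_like(x)]).T
        # normal equations, solved independently
        slope, intercept = np.linalg.solve(X.T @ X, X.T @ noisy.mean[:, 0])
        assert fit.b_ge[0] == pytest.approx(-slope, rel=1e-10)
        assert math.log(fit.a_ge[0]) == pytest.approx(intercept, rel=1e-10)
        slope_b, intercept_b = np.linalg.solve(X.T @ X,
                                               X.T @ noisy.mean[:, 1])
        assert fit.c_ge[0] == pytest.approx(slope_b, rel=1e-10)
        assert fit.d_ge[0] == pytest.approx(intercept_b, rel=1e-8)


class TestQ10Fit:
    def test_doubling_per_ten_kelvin(self):
        q10 = np.array([2.0, 2.0, 2.0, 2.0])
        alpha = np.array([1e-4, 1e-5, 0.1, 1e-2])
        beta = np.array([0.07, 0.05, 0.01, 0.03])
        fit = ht.fit_q10(q10_series(q10, alpha, beta))
        np.testing.assert_allclose(fit.q10, 2.0, rtol=1e-10)
        np.testing.assert_allclose(fit.a_q10, math.log(2.0) / 10.0,
                                   rtol=1e-10)
        np.testing.assert_allclose(fit.alpha, alpha, rtol=1e-10)
        np.testing.assert_allclose(fit.beta, beta, rtol=1e-12)

    def test_constant_prefactor_gives_unity(self):
        fit = ht.fit_q10(q10_series(np.ones(4), np.full(4, 1e-3),
                                    np.full(4, 0.05)))
        np.testing.assert_allclose(fit.q10, 1.0, rtol=1e-10)

    def test_noisy_fit_matches_direct_minimisation_oracle(self):
        rng = np.random.default_rng(8)
        series = q10_series(np.full(4, 3.0), np.full(4, 1e-3),
                            np.full(4, 0.05))
        noisy = EyringPlotSeries(
            TEMPS_K, series.mean + rng.normal(0, 0.03, series.mean.shape),
            series.sd)
        fit = ht.fit_q10(noisy)
        # oracle: minimise the Eyring-ordinate objective directly
        y = noisy.mean[:, 0]
        x = 1.0 / TEMPS_K

        def loss(p):
            return np.sum((y - q10_log_a_over_t(p[0], p[1], x)) ** 2)
        res = optimize.minimize(loss, [math.log(3.0) / 10.0, 0.0],
                                method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-14})
        assert fit.a_q10[0] == pytest.approx(res.x[0], abs=1e-6)

    def test_missing_reference_temperature(self):
        series = q10_series(np.ones(4), np.full(4, 1e-3), np.full(4, 0.05),
                            temps=np.array([300.0, 305.0, 310.0]))
        with pytest.raises(ValueError):
            ht.fit_q10(series, tref=298.15)


class TestPredictParameters:
    def test_ge_interpolation_identity(self, temp_truth):
        series = series_from_ge_coefficients(
            temp_truth.a_ge, temp_truth.b_ge, temp_truth.c_ge,
            temp_truth.d_ge, TEMPS_K)
        fit = ht.fit_generalized_eyring(series)
        for i, T in enumerate(TEMPS_K):
            p, _ = ht.predict_parameters(fit, T)
            truth_p = ht.parameters_at_temperature(
                temp_truth, T).as_vector()[1:]
            np.testing.assert_allclose(p, truth_p, rtol=1e-9)

    def test_q10_sensitivities_constant_in_temperature(self):
        fit = ht.fit_q10(q10_series(np.full(4, 2.5), np.full(4, 1e-3),
                                    np.array([0.07, 0.05, 0.01, 0.03])))
        p1, _ = ht.predict_parameters(fit, TEMPS_K[0])
        p2, _ = ht.predict_parameters(fit, TEMPS_K[-1])
        np.testing.assert_array_equal(p1[[1, 3, 5, 7]], p2[[1, 3, 5, 7]])

    def test_ge_sensitivity_tends_to_intercept(self, temp_truth):
        series = series_from_ge_coefficients(
            temp_truth.a_ge, temp_truth.b_ge, temp_truth.c_ge,
            temp_truth.d_ge, TEMPS_K)
        fit = ht.fit_generalized_eyring(series)
        b_far = fit.predict_B(np.array([1e9]))[:, 0]
        np.testing.assert_allclose(b_far, fit.d_ge, atol=1e-6)

    def test_warns_outside_calibrated_range(self, temp_truth):
        series = series_from_ge_coefficients(
            temp_truth.a_ge, temp_truth.b_ge, temp_truth.c_ge,
            temp_truth.d_ge, TEMPS_K)
        fit = ht.fit_generalized_eyring(series)
        with pytest.warns(UserWarning):
            ht.predict_parameters(fit, 400.0)


class TestTypicalEyring:
    def make_series(self, d_ge, noise_sd, seed=0):
        rng = np.random.default_rng(seed)
        series = series_from_ge_coefficients(
            np.full(4, 1e3), np.full(4, 8000.0), np.full(4, 25.0),
            np.full(4, d_ge), TEMPS_K)
        return EyringPlotSeries(
            TEMPS_K, series.mean + rng.normal(0, noise_sd,
                                              series.mean.shape),
            series.sd)

    def test_accepts_zero_intercept_data(self):
        fit = ht.fit_generalized_eyring(self.make_series(0.0, 1e-4))
        out = ht.typical_eyring_assessment(fit)
        assert all(a.holds for a in out)

    def test_rejects_large_intercept(self):
        fit = ht.fit_generalized_eyring(self.make_series(-0.05, 1e-5))
        out = ht.typical_eyring_assessment(fit)
        assert not any(a.holds for a in out)

    def test_matches_textbook_t_statistic(self):
        series = self.make_series(-0.004, 2e-3, seed=42)
        fit = ht.fit_generalized_eyring(series)
        out = ht.typical_eyring_assessment(fit)
        # independent OLS inference via scipy.linregress + t quantile
        reg = stats.linregress(1.0 / TEMPS_K, series.mean[:, 1])
        tcrit = stats.t.ppf(0.975, len(TEMPS_K) - 2)
        holds = abs(reg.intercept) <= tcrit * reg.intercept_stderr
        assert out[0].holds == holds
        assert out[0].se == pytest.approx(reg.intercept_stderr, rel=1e-12)

    def test_constrained_fit_has_zero_intercept(self):
        series = self.make_series(-0.02, 0.0)
        te = ht.fit_typical_eyring(series)
        # through-origin slope differs from the unconstrained one
        ge = ht.fit_generalized_eyring(series)
        assert not np.allclose(te.c_ge, ge.c_ge)


class TestPhysicalInterpretation:
    def ge_fit(self, a, b, c, d):
        series = series_from_ge_coefficients(
            np.full(4, a), np.full(4, b), np.full(4, c), np.full(4, d),
            TEMPS_K)
        return ht.fit_generalized_eyring(series)

    def test_entropy_zero_at_boltzmann_over_planck(self):
        a_ms = CONSTANTS.kB / CONSTANTS.h / 1000.0  # 1/(ms K)
        phys = ht.physical_interpretation(self.ge_fit(a_ms, 5e3, 30.0, -0.1))
        np.testing.assert_allclose(phys.delta_S, 0.0, atol=1e-8)

    def test_round_trip_identity(self, temp_truth):
        series = series_from_ge_coefficients(
            temp_truth.a_ge, temp_truth.b_ge, temp_truth.c_ge,
            temp_truth.d_ge, TEMPS_K)
        fit = ht.fit_generalized_eyring(series)
        a, b, c, d = ht.physical_to_reduced(ht.physical_interpretation(fit))
        np.testing.assert_allclose(a, fit.a_ge, rtol=1e-10)
        np.testing.assert_allclose(b, fit.b_ge, rtol=1e-10)
        np.testing.assert_allclose(c, fit.c_ge, rtol=1e-10)
        np.testing.assert_allclose(d, fit.d_ge, rtol=1e-10)

    def test_hand_evaluation_with_codata_constants(self):
        fit = self.ge_fit(2.0, 9000.0, 40.0, -0.08)
        phys = ht.physical_interpretation(fit)
        R, F = CONSTANTS.R, CONSTANTS.F
        assert phys.delta_H[0] == pytest.approx(R * 9000.0, rel=1e-10)
        assert phys.z_e[0] == pytest.approx(40.0 * 1000.0 * R / F,
                                            rel=1e-10)
        assert phys.delta_S[0] == pytest.approx(
            R * math.log(2000.0 * CONSTANTS.h / CONSTANTS.kB), rel=1e-10)
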