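"""Temperature models of the kinetic parameters: Eyring and Q10.

Every transition rate has the form k = A * exp(B*V).  On an "Eyring plot"
— ln(A/T) and B against 1/T — the three candidate temperature models are

* Generalized Eyring:  ln(A/T) = ln(a_GE) - b_GE / T,  B = c_GE / T + d_GE
  (both straight lines in 1/T);
* Typical Eyring: the special case d_GE = 0, forcing the B line through
  the origin;
* Q10:  ln A = a_Q10 * T + c_Q10 with a_Q10 = ln(Q10)/10, so ln(A/T) is a
  mild curve in 1/T, and B is a temperature-independent constant.

This module transforms per-temperature parameter estimates to the Eyring
plot, fits each model by (linear) least squares — once to the means and
once to the SDs of the per-temperature distributions — and predicts
parameters at new temperatures.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import CONSTANTS

__all__ = [
    "EyringPlotSeries",
    "GeneralizedEyringFit",
    "TypicalEyringFit",
    "Q10Fit",
    "PhysicalEyringParameters",
    "TypicalEyringAssessment",
    "to_eyring_plot",
    "series_from_ge_coefficients",
    "fit_generalized_eyring",
    "fit_typical_eyring",
    "fit_q10",
    "predict_parameters",
    "typical_eyring_assessment",
    "physical_interpretation",
    "physical_to_reduced",
    "ge_log_a_over_t",
    "q10_log_a_over_t",
]

# Column layout of the 8 kinetic parameters p1..p8; per rate (A, B) columns.
RATE_COLUMNS = {1: (0, 1), 2: (2, 3), 3: (4, 5), 4: (6, 7)}
A_COLUMNS = (0, 2, 4, 6)
B_COLUMNS = (1, 3, 5, 7)
RATE_NAMES = ("k1", "k2", "k3", "k4")


@dataclass(frozen=True)
class EyringPlotSeries:
    """Per-temperature summaries of the parameters in Eyring-plot form.

    ``mean``/``sd`` have shape (n_temperatures, 8) with columns p1..p8.
    A-type columns hold ln(p/T); B-type columns hold p itself.
    """

    temps_K: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.temps_K, dtype=float)
        m = np.asarray(self.mean, dtype=float)
        s = np.asarray(self.sd, dtype=float)
        if len(t) < 2:
            raise ValueError("need at least 2 temperatures")
        if m.shape != (len(t), 8) or s.shape != m.shape:
            raise ValueError("mean/sd must have shape (n_temps, 8)")
        if np.any(s < 0):
            raise ValueError("SDs must be non-negative")
        if len(np.unique(t)) != len(t):
            raise ValueError("temperatures must be distinct")
        order = np.argsort(t)
        object.__setattr__(self, "temps_K", t[order])
        object.__setattr__(self, "mean", m[order])
        object.__setattr__(self, "sd", s[order])

    @property
    def inv_T(self) -> np.ndarray:
        return 1.0 / self.temps_K


def to_eyring_plot(temps_K, samples_per_temperature) -> EyringPlotSeries:
    """Transform per-temperature posterior samples to Eyring-plot form.

    ``samples_per_temperature`` is one array per temperature of shape
    (n, 9) (log-parameter samples, conductance in column 0, which is
    dropped) or (n, 8).  For prefactor columns the ordinate is
    ln(p/T) = phi - ln T; for sensitivity columns it is p = exp(phi).
    Means and SDs are taken across the samples.
    """
    temps_K = np.asarray(temps_K, dtype=float)
    if len(temps_K) != len(samples_per_temperature):
        raise ValueError("one sample array per temperature required")
    means = np.empty((len(temps_K), 8))
    sds = np.empty_like(means)
    for i, (T, samp) in enumerate(zip(temps_K, samples_per_temperature)):
        samp = np.asarray(samp, dtype=float)
        if samp.ndim != 2 or samp.shape[1] not in (8, 9):
            raise ValueError("samples must be (n, 8) or (n, 9) arrays")
        phi = samp[:, 1:] if samp.shape[1] == 9 else samp
        y = np.empty_like(phi)
        y[:, list(A_COLUMNS)] = phi[:, list(A_COLUMNS)] - math.log(T)
        y[:, list(B_COLUMNS)] = np.exp(phi[:, list(B_COLUMNS)])
        means[i] = y.mean(axis=0)
        sds[i] = y.std(axis=0, ddof=1) if len(y) > 1 else 0.0
    return EyringPlotSeries(temps_K, means, sds)


def series_from_ge_coefficients(a_ge, b_ge, c_ge, d_ge,
                                temps_K) -> EyringPlotSeries:
    """Noise-free Eyring-plot series generated exactly from GE coefficients.

    Coefficient arrays are ordered (k1..k4); SDs are zero.
    """
    temps_K = np.asarray(temps_K, dtype=float)
    a_ge, b_ge, c_ge, d_ge = (np.asarray(x, dtype=float)
                              for x in (a_ge, b_ge, c_ge, d_ge))
    mean = np.empty((len(temps_K), 8))
    for rate, (ia, ib) in RATE_COLUMNS.items():
        i = rate - 1
        mean[:, ia] = np.log(a_ge[i]) - b_ge[i] / temps_K
        mean[:, ib] = c_ge[i] / temps_K + d_ge[i]
    return EyringPlotSeries(temps_K, mean, np.zeros_like(mean))


def _ols(x, y):
    """Least-squares line fit; returns slope, intercept."""
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return coef[0], coef[1]


@dataclass(frozen=True)
class GeneralizedEyringFit:
    """Per-rate Generalized Eyring coefficients (arrays ordered k1..k4).

    The ``sd_*`` arrays hold the same linear forms fitted to the SD
    series: sd of ln(A/T) modelled as sd_A_intercept + sd_A_slope / T;
    sd of B as sd_B_intercept + sd_B_slope / T.
    """

    a_ge: np.ndarray
    b_ge: np.ndarray
    c_ge: np.ndarray
    d_ge: np.ndarray
    d_ge_se: np.ndarray
    sd_A_slope: np.ndarray
    sd_A_intercept: np.ndarray
    sd_B_slope: np.ndarray
    sd_B_intercept: np.ndarray
    n_temps: int

    def predict_A(self, T):
        T = np.asarray(T, dtype=float)
        return self.a_ge[:, None] * T * np.exp(-self.b_ge[:, None] / T)

    def predict_B(self, T):
        T = np.asarray(T, dtype=float)
        return self.c_ge[:, None] / T + self.d_ge[:, None]

    def to_records(self):
        return [dict(rate=RATE_NAMES[i], model="generalized-eyring",
                     a_ge=float(self.a_ge[i]), b_ge=float(self.b_ge[i]),
                     c_ge=float(self.c_ge[i]), d_ge=float(self.d_ge[i]))
                for i in range(4)]


@dataclass(frozen=True)
class TypicalEyringFit:
    """Eyring fit with the B line constrained through the origin (D = 0)."""

    a_ge: np.ndarray
    b_ge: np.ndarray
    c_ge: np.ndarray

    def predict_B(self, T):
        return self.c_ge[:, None] / np.asarray(T, dtype=float)


@dataclass(frozen=True)
class Q10Fit:
    """Per-rate Q10 model (arrays ordered k1..k4).

    k = Q10^((T - Tref)/10) * alpha * exp(beta * V); internally
    a_q10 = ln(Q10)/10 and c_q10 = ln(alpha) - Tref*ln(Q10)/10.  B-type
    parameters are anchored at Tref (constant in temperature).
    """

    q10: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    tref: float
    a_q10: np.ndarray
    c_q10: np.ndarray
    sd_a_q10: np.ndarray
    sd_c_q10: np.ndarray
    beta_sd: np.ndarray

    def predict_A(self, T):
        T = np.asarray(T, dtype=float)
        return self.q10[:, None] ** ((T - self.tref) / 10.0) \
            * self.alpha[:, None]

    def predict_B(self, T):
        T = np.asarray(T, dtype=float)
        return np.broadcast_to(self.beta[:, None], (4, len(np.atleast_1d(T))))

    def to_records(self):
        return [dict(rate=RATE_NAMES[i], model="q10",
                     q10=float(self.q10[i]), alpha=float(self.alpha[i]),
                     beta=float(self.beta[i]), tref=self.tref)
                for i in range(4)]


def fit_generalized_eyring(series: EyringPlotSeries) -> GeneralizedEyringFit:
    """OLS fit of the Generalized Eyring lines to an Eyring-plot series.

    ln(A/T) regressed on 1/T gives (ln a_GE, -b_GE); B regressed on 1/T
    gives (c_GE, d_GE).  The SD series are fitted with the same linear
    forms.  The intercept standard error of the B regression (needs >= 3
    temperatures) supports the Typical-Eyring assessment.
    """
    x = series.inv_T
    if len(np.unique(x)) < 2:
        raise ValueError("regression needs >= 2 distinct temperatures")
    a_ge = np.empty(4)
    b_ge = np.empty(4)
    c_ge = np.empty(4)
    d_ge = np.empty(4)
    d_se = np.full(4, np.nan)
    sdA_m = np.empty(4)
    sdA_q = np.empty(4)
    sdB_m = np.empty(4)
    sdB_q = np.empty(4)
    for rate, (ia, ib) in RATE_COLUMNS.items():
        i = rate - 1
        m, q = _ols(x, series.mean[:, ia])
        a_ge[i], b_ge[i] = math.exp(q), -m
        if len(x) >= 3:
            reg = stats.linregress(x, series.mean[:, ib])
            c_ge[i], d_ge[i] = reg.slope, reg.intercept
            d_se[i] = reg.intercept_stderr
        else:
            c_ge[i], d_ge[i] = _ols(x, series.mean[:, ib])
        sdA_m[i], sdA_q[i] = _ols(x, series.sd[:, ia])
        sdB_m[i], sdB_q[i] = _ols(x, series.sd[:, ib])
    return GeneralizedEyringFit(
        a_ge=a_ge, b_ge=b_ge, c_ge=c_ge, d_ge=d_ge, d_ge_se=d_se,
        sd_A_slope=sdA_m, sd_A_intercept=sdA_q, sd_B_slope=sdB_m,
        sd_B_intercept=sdB_q, n_temps=len(x))


def fit_typical_eyring(series: EyringPlotSeries) -> TypicalEyringFit:
    """Eyring fit with d_GE constrained to 0 (B proportional to 1/T)."""
    x = series.inv_T
    a_ge = np.empty(4)
    b_ge = np.empty(4)
    c_ge = np.empty(4)
    for rate, (ia, ib) in RATE_COLUMNS.items():
        i = rate - 1
        m, q = _ols(x, series.mean[:, ia])
        a_ge[i], b_ge[i] = math.exp(q), -m
        y = series.mean[:, ib]
        c_ge[i] = float(x @ y / (x @ x))  # through-origin least squares
    return TypicalEyringFit(a_ge=a_ge, b_ge=b_ge, c_ge=c_ge)


def fit_q10(series: EyringPlotSeries, tref: float = 298.15) -> Q10Fit:
    """Least-squares Q10 fit to an Eyring-plot series.

    For the prefactors, ln A = a_Q10*T + c_Q10 is linear in T, so the
    least-squares problem on the Eyring ordinate reduces exactly to OLS of
    ln A on T (the ln T term cancels from the residuals).  The B-type
    parameters are constant under Q10 and are anchored to their mean and
    SD at the reference temperature, which must be one of the series'
    temperatures.
    """
    T = series.temps_K
    i_ref = int(np.argmin(np.abs(T - tref)))
    if abs(T[i_ref] - tref) > 1e-6:
        raise ValueError(
            f"series lacks the reference temperature {tref} K")
    a_q10 = np.empty(4)
    c_q10 = np.empty(4)
    sd_a = np.empty(4)
    sd_c = np.empty(4)
    beta = np.empty(4)
    beta_sd = np.empty(4)
    for rate, (ia, ib) in RATE_COLUMNS.items():
        i = rate - 1
        ln_A = series.mean[:, ia] + np.log(T)
        a_q10[i], c_q10[i] = _ols(T, ln_A)
        sd_lnA = series.sd[:, ia] + np.log(T)  # same Eyring-plot form
        sd_a[i], sd_c[i] = _ols(T, sd_lnA)
        beta[i] = series.mean[i_ref, ib]
        beta_sd[i] = series.sd[i_ref, ib]
    q10 = np.exp(10.0 * a_q10)
    alpha = np.exp(a_q10 * tref + c_q10)
    return Q10Fit(q10=q10, alpha=alpha, beta=beta, tref=tref, a_q10=a_q10,
                  c_q10=c_q10, sd_a_q10=sd_a, sd_c_q10=sd_c,
                  beta_sd=beta_sd)


def predict_parameters(fit, T: float):
    """Kinetic parameters (p1..p8, positive scale) predicted at T kelvin.

    Returns (p_mean, p_spread): ``p_mean`` is the 8-vector of predicted
    parameters; ``p_spread`` holds the SD-fit evaluated at T — in log
    units for prefactor entries (SD of ln A) and in parameter units for
    sensitivity entries.
    """
    if not 250.0 <= T <= 330.0:
        warnings.warn(f"T = {T} K outside the calibrated range 250-330 K")
    p = np.empty(8)
    s = np.empty(8)
    A = fit.predict_A([T])[:, 0]
    B = fit.predict_B([T])[:, 0]
    for rate, (ia, ib) in RATE_COLUMNS.items():
        i = rate - 1
        p[ia], p[ib] = A[i], B[i]
        if isinstance(fit, GeneralizedEyringFit):
            s[ia] = fit.sd_A_intercept[i] + fit.sd_A_slope[i] / T
            s[ib] = fit.sd_B_intercept[i] + fit.sd_B_slope[i] / T
        elif isinstance(fit, Q10Fit):
            s[ia] = fit.sd_a_q10[i] * T + fit.sd_c_q10[i] - math.log(T)
            s[ib] = fit.beta_sd[i]
        else:
            s[ia] = s[ib] = np.nan
    return p, s


@dataclass(frozen=True)
class TypicalEyringAssessment:
    rate: str
    d_ge: float
    se: float
    ci: tuple
    holds: bool


def typical_eyring_assessment(fit: GeneralizedEyringFit,
                              level: float = 0.95):
    """Does d_GE = 0 (Typical Eyring) survive per rate?

    Uses the OLS intercept standard error with a t confidence band;
    requires >= 3 temperatures for a residual-based error estimate.
    """
    if fit.n_temps < 3 or np.any(~np.isfinite(fit.d_ge_se)):
        raise ValueError("assessment needs >= 3 temperatures")
    dof = fit.n_temps - 2
    tcrit = stats.t.ppf(0.5 + level / 2.0, dof)
    out = []
    for i in range(4):
        half = tcrit * fit.d_ge_se[i]
        ci = (fit.d_ge[i] - half, fit.d_ge[i] + half)
        out.append(TypicalEyringAssessment(
            rate=RATE_NAMES[i], d_ge=float(fit.d_ge[i]),
            se=float(fit.d_ge_se[i]), ci=ci, holds=ci[0] <= 0.0 <= ci[1]))
    return out


@dataclass(frozen=True)
class PhysicalEyringParameters:
    """Thermodynamic reading of GE coefficients (arrays ordered k1..k4).

    delta_S in J/(mol K), delta_H in J/mol, z_e dimensionless, D in 1/mV.
    Conversions account for the package units (rates 1/ms, voltages mV).
    """

    delta_S: np.ndarray
    delta_H: np.ndarray
    z_e: np.ndarray
    D: np.ndarray


def physical_interpretation(fit: GeneralizedEyringFit
                            ) -> PhysicalEyringParameters:
    """Map (a_GE, b_GE, c_GE, d_GE) to (delta_S, delta_H, z_e, D).

    a_GE = (kB/h) exp(delta_S/R) with rates in 1/s, so the 1/ms prefactor
    is multiplied by 1000; c_GE = z_e*F/R with voltage in volts, so the
    K/mV value is likewise rescaled.
    """
    if np.any(fit.a_ge <= 0):
        raise ValueError("a_ge must be positive")
    C = CONSTANTS
    a_per_s = fit.a_ge * 1000.0
    c_per_V = fit.c_ge * 1000.0
    return PhysicalEyringParameters(
        delta_S=C.R * np.log(a_per_s * C.h / C.kB),
        delta_H=C.R * fit.b_ge,
        z_e=c_per_V * C.R / C.F,
        D=fit.d_ge.copy())


def physical_to_reduced(phys: PhysicalEyringParameters):
    """Inverse of :func:`physical_interpretation`; returns (a,b,c,d)_GE."""
    C = CONSTANTS
    a_ge = (C.kB / C.h) * np.exp(phys.delta_S / C.R) / 1000.0
    b_ge = phys.delta_H / C.R
    c_ge = phys.z_e * C.F / C.R / 1000.0
    return a_ge, b_ge, c_ge, phys.D.copy()


def ge_log_a_over_t(ln_a_ge: float, b_ge: float, inv_T):
    """Generalized/Typical Eyring ordinate ln(A/T) at 1/T."""
    return ln_a_ge - b_ge * np.asarray(inv_T, dtype=float)


def q10_log_a_over_t(a_q10: float, c_q10: float, inv_T):
    """Q10 ordinate ln(A/T) = a_Q10/x + ln(x) + c_Q10 with x = 1/T."""
    x = np.asarray(inv_T, dtype=float)
    return a_q10 / x + np.log(x) + c_q10
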