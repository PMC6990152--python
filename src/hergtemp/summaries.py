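"""Validation metrics, trace normalisation, and the Q10 protocol study.

Includes the relative root-mean-square error (RRMSE) used to score fits
and predictions, the two normalisation procedures used for visual
comparison of wells (least-squares scaling to a reference trace, and a
conductance estimate from back-extrapolating the tail current after a
+40 -> -120 mV step), and a simulator of classical Q10-estimation
experiments: a gating process is probed with a voltage protocol at two
temperatures, a time constant is extracted by exponential fitting of a
trace segment, and Q10 = (tau_cold / tau_hot)^(10 / delta_T).

Because the model's voltage sensitivities change with temperature, the
estimated Q10 depends on the probing voltage — i.e. on the protocol —
which is the study this module exists to run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .model import IonicConditions, KineticParameters, reversal_potential
from .protocols import StepProtocol
from .simulate import CurrentTrace, simulate_step_analytic

__all__ = [
    "rrmse",
    "rrmse_summary",
    "normalize_to_reference",
    "normalize_by_tail_extrapolation",
    "fit_exponential",
    "ExponentialFitError",
    "Q10ExperimentSpec",
    "Q10Estimate",
    "zhou_style_specs",
    "vandenberg_style_specs",
    "estimate_q10",
    "direct_q10_from_fit",
    "build_q10_report",
    "PROCESS_RATE",
]


class ExponentialFitError(RuntimeError):
    pass


def rrmse(model, data) -> float:
    """Relative RMSE: sqrt(sum((model-data)^2) / sum(data^2))."""
    model = np.asarray(model, dtype=float)
    data = np.asarray(data, dtype=float)
    if model.shape != data.shape:
        raise ValueError("model/data length mismatch")
    denom = float(np.sum(data ** 2))
    if denom == 0.0:
        raise ZeroDivisionError("data trace has zero energy")
    return math.sqrt(float(np.sum((model - data) ** 2)) / denom)


def rrmse_summary(values):
    """(best, median, 90th percentile) of a set of RRMSE values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one RRMSE value")
    return (float(np.min(values)), float(np.median(values)),
            float(np.percentile(values, 90.0)))  # linear interpolation


def normalize_to_reference(trace, reference, mode: str = "ls"):
    """Scale a trace onto a reference; returns (scaled, scale factor).

    'ls' minimises the squared difference (closed form
    s = <x, ref> / <x, x>); 'abs' minimises the summed absolute
    difference by 1-D search.
    """
    x = np.asarray(trace, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if x.shape != ref.shape:
        raise ValueError("trace/reference length mismatch")
    xx = float(x @ x)
    if xx == 0.0:
        raise ZeroDivisionError("cannot normalise an identically-zero trace")
    if mode == "ls":
        s = float(x @ ref) / xx
    elif mode == "abs":
        s_ls = float(x @ ref) / xx
        res = optimize.minimize_scalar(
            lambda s: float(np.sum(np.abs(s * x - ref))),
            bracket=(0.0, s_ls if s_ls != 0 else 1.0))
        s = float(res.x)
    else:
        raise ValueError("mode must be 'ls' or 'abs'")
    return s * x, s


def fit_exponential(t, y, n_exp: int = 1):
    """Fit y(t) = c + sum_i b_i * exp(-t/tau_i) by nonlinear least squares.

    Initialised from a log-linear regression of the detrended segment.
    Returns (taus, bs, c) with taus sorted descending (slowest first).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 4 + 2 * n_exp:
        raise ExponentialFitError("too few samples for an exponential fit")
    t = t - t[0]
    c0 = y[-1]
    b0 = y[0] - c0
    if b0 == 0.0:
        b0 = (np.max(y) - np.min(y)) or 1.0
    resid = y - c0
    mask = np.abs(resid) > 0.05 * abs(b0)
    if mask.sum() >= 3:
        slope, _ = np.polyfit(t[mask], np.log(np.abs(resid[mask]) + 1e-300), 1)
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    else:
        tau0 = (t[-1] - t[0]) / 3.0
    tau0 = min(max(tau0, 1e-3), 100 * (t[-1] + 1e-9))

    if n_exp == 1:
        def f(t, b, tau, c):
            return c + b * np.exp(-t / tau)
        p0 = [b0, tau0, c0]
        lb = [-np.inf, 1e-6, -np.inf]
        ub = [np.inf, np.inf, np.inf]
    elif n_exp == 2:
        def f(t, b1, tau1, b2, tau2, c):
            return c + b1 * np.exp(-t / tau1) + b2 * np.exp(-t / tau2)
        p0 = [0.7 * b0, tau0, 0.3 * b0, tau0 / 10.0, c0]
        lb = [-np.inf, 1e-6, -np.inf, 1e-6, -np.inf]
        ub = [np.inf] * 5
    else:
        raise ValueError("n_exp must be 1 or 2")
    try:
        popt, _ = optimize.curve_fit(f, t, y, p0=p0, bounds=(lb, ub),
                                     maxfev=20000)
    except Exception as exc:
        raise ExponentialFitError(f"exponential fit failed: {exc}") from exc
    if n_exp == 1:
        return np.array([popt[1]]), np.array([popt[0]]), float(popt[2])
    taus = np.array([popt[1], popt[3]])
    bs = np.array([popt[0], popt[2]])
    order = np.argsort(taus)[::-1]
    return taus[order], bs[order], float(popt[4])


def normalize_by_tail_extrapolation(trace: CurrentTrace,
                                    protocol: StepProtocol,
                                    cond: IonicConditions,
                                    skip_ms: float = 20.0,
                                    window_ms: float = 80.0) -> float:
    """Conductance scale from the tail current after a +40 -> -120 mV step.

    Fits a single exponential to the tail current at -120 mV (after
    ``skip_ms``, letting the fast inactivation gate recover) and
    extrapolates it back to the instant of the step; dividing by the
    driving force (-120 - E_K) under the approximation a ~ 1 at the end
    of the +40 mV step yields an estimate of g_Kr.
    """
    b = protocol.boundaries
    t_step = None
    for i in range(1, len(protocol.segments)):
        v_prev = protocol.segments[i - 1][1]
        v_here = protocol.segments[i][1]
        if v_prev >= 30.0 and v_here <= -110.0:
            t_step = b[i]
            break
    if t_step is None:
        raise ValueError("protocol lacks a +40 -> -120 mV transition")
    t0 = t_step + skip_ms
    mask = (trace.times >= t0) & (trace.times < t0 + window_ms)
    if mask.sum() < 10:
        raise ValueError("tail window must contain at least 10 samples")
    taus, bs, c = fit_exponential(trace.times[mask], trace.currents[mask])
    # extrapolate the fitted exponential back to the step instant
    value_at_step = c + float(bs[0] * np.exp((t0 - t_step) / taus[0]))
    EK = reversal_potential(cond)
    return value_at_step / (-120.0 - EK)


# ---------------------------------------------------------------------------
# Q10 protocol-dependence study

PROCESS_RATE = {"activation": "k1", "deactivation": "k2",
                "inactivation": "k3", "recovery": "k4"}


@dataclass(frozen=True)
class Q10ExperimentSpec:
    """One classical Q10-estimation experiment.

    The named gating process is probed with ``protocol``; the time
    constant is extracted by fitting ``n_exp`` exponential(s) to the
    samples of segment ``fit_segment`` starting ``skip_ms`` after the
    segment begins (``window_ms`` long, or to the segment end).
    """

    name: str
    process: str
    protocol: StepProtocol
    fit_segment: int
    skip_ms: float = 0.0
    window_ms: float | None = None
    n_exp: int = 1
    dt: float = 0.1
    fit_to_peak: bool = False  # fit only up to the |I| peak (rising hooks)

    def __post_init__(self):
        if self.process not in PROCESS_RATE:
            raise ValueError(f"unknown process {self.process!r}")
        if not 0 <= self.fit_segment < len(self.protocol.segments):
            raise ValueError("fit segment outside protocol")


def zhou_style_specs() -> dict:
    """Step-protocol Q10 specs in the style of a 0/-50 mV probing study.

    Documented approximations: activation as the current rise during a
    long 0 mV step; deactivation as the tail decay at -50 mV; the
    inactivation pair probed at +40 mV after a brief -120 mV recovery
    interval; recovery as the tail hook at -120 mV.
    """
    return {
        "activation": Q10ExperimentSpec(
            "zhou-activation", "activation",
            StepProtocol.from_steps([(500.0, -80.0), (10000.0, 0.0)]),
            fit_segment=1, skip_ms=300.0, dt=1.0),
        "deactivation": Q10ExperimentSpec(
            "zhou-deactivation", "deactivation",
            StepProtocol.from_steps([(500.0, -80.0), (1000.0, 60.0),
                                     (12000.0, -50.0)]),
            fit_segment=2, skip_ms=100.0, dt=1.0),
        "inactivation": Q10ExperimentSpec(
            "zhou-inactivation", "inactivation",
            StepProtocol.from_steps([(500.0, -80.0), (1000.0, 40.0),
                                     (15.0, -120.0), (100.0, 40.0)]),
            fit_segment=3, skip_ms=0.5, dt=0.02),
        "recovery": Q10ExperimentSpec(
            "zhou-recovery", "recovery",
            StepProtocol.from_steps([(500.0, -80.0), (1000.0, 40.0),
                                     (60.0, -120.0)]),
            fit_segment=2, skip_ms=0.1, window_ms=30.0, dt=0.02,
            fit_to_peak=True),
    }


def vandenberg_style_specs() -> dict:
    """Q10 specs in the style of a +40/-70/-90 mV probing study."""
    return {
        "activation": Q10ExperimentSpec(
            "vandenberg-activation", "activation",
            StepProtocol.from_steps([(500.0, -80.0), (6000.0, 40.0)]),
            fit_segment=1, skip_ms=100.0, dt=1.0),
        "deactivation": Q10ExperimentSpec(
            "vandenberg-deactivation", "deactivation",
            StepProtocol.from_steps([(500.0, -80.0), (1000.0, 40.0),
                                     (8000.0, -70.0)]),
            fit_segment=2, skip_ms=60.0, dt=1.0),
        "inactivation": Q10ExperimentSpec(
            "vandenberg-inactivation", "inactivation",
            StepProtocol.from_steps([(500.0, -80.0), (1000.0, 40.0),
                                     (4.0, -120.0), (60.0, 60.0)]),
            fit_segment=3, skip_ms=0.3, window_ms=25.0, dt=0.02),
        "recovery": Q10ExperimentSpec(
            "vandenberg-recovery", "recovery",
            StepProtocol.from_steps([(500.0, -80.0), (1000.0, 40.0),
                                     (120.0, -90.0)]),
            fit_segment=2, skip_ms=0.1, window_ms=60.0, dt=0.02,
            fit_to_peak=True),
    }


@dataclass(frozen=True)
class Q10Estimate:
    q10: float
    tau_cold: float
    tau_hot: float
    spec_name: str
    process: str


def _extract_tau(params: KineticParameters, spec: Q10ExperimentSpec,
                 cond: IonicConditions, temperature_label: str) -> float:
    trace = simulate_step_analytic(params, spec.protocol, cond, dt=spec.dt)
    b = spec.protocol.boundaries
    t0 = b[spec.fit_segment] + spec.skip_ms
    t1 = b[spec.fit_segment + 1] if spec.window_ms is None \
        else min(t0 + spec.window_ms, b[spec.fit_segment + 1])
    mask = (trace.times >= t0) & (trace.times < t1)
    if spec.fit_to_peak:
        # restrict to the monotone phase up to the |I| extremum (the
        # recovery "hook"); the later decay follows a different gate
        idx = np.flatnonzero(mask)
        seg = np.abs(trace.currents[idx])
        peak = int(np.argmax(seg))
        if peak < 6:
            raise ExponentialFitError(
                f"{spec.name}: too few rising samples before the peak")
        mask = np.zeros_like(mask)
        mask[idx[:peak + 1]] = True
    try:
        taus, _, _ = fit_exponential(trace.times[mask],
                                     trace.currents[mask], n_exp=spec.n_exp)
    except ExponentialFitError as exc:
        raise ExponentialFitError(
            f"{spec.name}: fit failed at {temperature_label} in segment "
            f"{spec.fit_segment}") from exc
    return float(taus[0])


def estimate_q10(params_cold: KineticParameters,
                 params_hot: KineticParameters,
                 spec: Q10ExperimentSpec,
                 t_cold_C: float = 25.0, t_hot_C: float = 37.0,
                 Ko: float = 4.0, Ki: float = 110.0) -> Q10Estimate:
    """Protocol-based Q10 estimate for one gating process.

    Simulates the spec's protocol with the cold and hot parameter sets,
    extracts the time constant by exponential fitting, and returns
    Q10 = (tau_cold / tau_hot)^(10 / (t_hot - t_cold)).
    """
    if t_hot_C == t_cold_C:
        raise ValueError("temperatures must be distinct")
    cond_cold = IonicConditions.at_celsius(t_cold_C, Ko=Ko, Ki=Ki)
    cond_hot = IonicConditions.at_celsius(t_hot_C, Ko=Ko, Ki=Ki)
    tau_c = _extract_tau(params_cold, spec, cond_cold, f"{t_cold_C} C")
    tau_h = _extract_tau(params_hot, spec, cond_hot, f"{t_hot_C} C")
    q10 = (tau_c / tau_h) ** (10.0 / (t_hot_C - t_cold_C))
    return Q10Estimate(q10=float(q10), tau_cold=tau_c, tau_hot=tau_h,
                       spec_name=spec.name, process=spec.process)


def direct_q10_from_fit(q10fit, rate) -> float:
    """The fitted Q10 coefficient for one rate (name 'k1'..'k4' or 1..4)."""
    names = {"k1": 0, "k2": 1, "k3": 2, "k4": 3}
    if isinstance(rate, str):
        if rate not in names:
            raise KeyError(f"unknown rate {rate!r}; expected k1..k4")
        idx = names[rate]
    else:
        if rate not in (1, 2, 3, 4):
            raise KeyError("rate index must be 1..4")
        idx = rate - 1
    return float(q10fit.q10[idx])


def build_q10_report(estimates, direct_fit=None) -> pd.DataFrame:
    """Tabulate protocol-based Q10 estimates next to the direct fit.

    ``estimates`` is an iterable of Q10Estimate; ``direct_fit`` an
    optional Q10Fit whose per-rate coefficients are added as a
    'direct-fit' column (matched to each process through the rate that
    governs it).
    """
    rows = {}
    for est in estimates:
        family = est.spec_name.removesuffix("-" + est.process) or est.spec_name
        rows.setdefault(est.process, {})[family] = est.q10
    if direct_fit is not None:
        for process, rate in PROCESS_RATE.items():
            if process in rows:
                rows[process]["direct-fit"] = direct_q10_from_fit(
                    direct_fit, rate)
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "process"
    return df
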