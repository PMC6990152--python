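"""Forward simulation of the hERG model under voltage-clamp protocols.

Two integration paths are provided:

* :func:`simulate_step_analytic` — exact piecewise-analytic propagation.
  Within a constant-voltage segment each Hodgkin-Huxley gate relaxes as
  ``x(t) = x_inf - (x_inf - x0) * exp(-t / tau)``, so step protocols can be
  integrated without a numerical solver.  This is the fast path used in
  fitting and sampling.
* :func:`simulate_ode` — stiff-ODE integration (scipy ``solve_ivp``), the
  general path that also handles ramps and sampled waveforms, with default
  tolerances abs 1e-8 / rel 1e-10.

The two paths agree to solver tolerance on step protocols; that
cross-check is the module's central test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .model import (GateState, IonicConditions, KineticParameters,
                    reversal_potential, steady_states, transition_rates)
from .protocols import SampledProtocol, StepProtocol

__all__ = [
    "CurrentTrace",
    "SolverSettings",
    "IntegrationError",
    "UnsupportedSegmentError",
    "default_initial_state",
    "simulate_step_analytic",
    "simulate_ode",
]

DEFAULT_DT = 0.1  # ms; typical patch-clamp sampling interval


class IntegrationError(RuntimeError):
    pass


class UnsupportedSegmentError(ValueError):
    pass


@dataclass(frozen=True)
class SolverSettings:
    abs_tol: float = 1e-8
    rel_tol: float = 1e-10
    max_step: float | None = None
    dt: float = DEFAULT_DT

    def __post_init__(self):
        if self.abs_tol <= 0 or self.rel_tol <= 0 or self.dt <= 0:
            raise ValueError("tolerances and dt must be positive")


@dataclass
class CurrentTrace:
    """Sampled current (and optionally commanded voltage) for one well."""

    times: np.ndarray
    currents: np.ndarray
    voltages: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.voltages is not None:
            self.voltages = np.asarray(self.voltages, dtype=float)
            if self.voltages.shape != self.times.shape:
                raise ValueError("voltage array length mismatch")
        if self.times.shape != self.currents.shape:
            raise ValueError("times/currents length mismatch")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def to_csv(self, path, sidecar=True):
        path = Path(path)
        cols = "t_ms,i" + (",v_mV" if self.voltages is not None else "")
        arrays = [self.times, self.currents]
        if self.voltages is not None:
            arrays.append(self.voltages)
        with open(path, "w") as f:
            f.write(cols + "\n")
            for row in zip(*arrays):
                f.write(",".join(f"{x:.17g}" for x in row) + "\n")
        if sidecar and self.metadata:
            with open(path.with_suffix(path.suffix + ".json"), "w") as f:
                json.dump(self.metadata, f, indent=2)

    @classmethod
    def from_csv(cls, path) -> "CurrentTrace":
        path = Path(path)
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        voltages = data[:, 2] if data.shape[1] > 2 else None
        metadata = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            with open(sidecar) as f:
                metadata = json.load(f)
        return cls(data[:, 0], data[:, 1], voltages, metadata)


def default_initial_state(params: KineticParameters,
                          holding_voltage: float) -> GateState:
    """Gates pre-equilibrated at the holding voltage."""
    if not np.isfinite(holding_voltage):
        raise ValueError("holding voltage must be finite")
    a_inf, r_inf = steady_states(params, holding_voltage)
    return GateState(float(a_inf), float(r_inf))


def _sample_times(total_duration: float, dt: float) -> np.ndarray:
    n = int(np.floor(total_duration / dt + 1e-9))
    return np.arange(n) * dt


def simulate_step_analytic(params: KineticParameters,
                           protocol: StepProtocol,
                           cond: IonicConditions | None = None,
                           initial_state: GateState | None = None,
                           dt: float = DEFAULT_DT) -> CurrentTrace:
    """Exact simulation of a step-only protocol.

    Gates follow their mono-exponential relaxation within each segment and
    are chained exactly across segment boundaries; the current is then
    I = g * a * r * (V - E_K) at samples t = 0, dt, 2*dt, ...
    """
    if not isinstance(protocol, StepProtocol):
        raise UnsupportedSegmentError(
            "analytic path requires a StepProtocol; use simulate_ode")
    if not protocol.is_step_only:
        raise UnsupportedSegmentError(
            "protocol contains ramp segments; use simulate_ode")
    if dt <= 0:
        raise ValueError("dt must be positive")
    cond = cond or IonicConditions()
    EK = reversal_potential(cond)
    if initial_state is None:
        initial_state = default_initial_state(params, protocol.segments[0][1])

    times = _sample_times(protocol.total_duration, dt)
    a_out = np.empty_like(times)
    r_out = np.empty_like(times)
    v_out = np.empty_like(times)

    a0, r0 = initial_state.a, initial_state.r
    t_seg_start = 0.0
    idx0 = 0
    for duration, v, _ in protocol.segments:
        t_seg_end = t_seg_start + duration
        idx1 = int(np.searchsorted(times, t_seg_end - 1e-12, side="left"))
        k1, k2, k3, k4 = transition_rates(params, v)
        a_inf, tau_a = k1 / (k1 + k2), 1.0 / (k1 + k2)
        r_inf, tau_r = k4 / (k3 + k4), 1.0 / (k3 + k4)
        tl = times[idx0:idx1] - t_seg_start
        a_out[idx0:idx1] = a_inf - (a_inf - a0) * np.exp(-tl / tau_a)
        r_out[idx0:idx1] = r_inf - (r_inf - r0) * np.exp(-tl / tau_r)
        v_out[idx0:idx1] = v
        # exact state at the segment end, independent of the sample grid
        a0 = a_inf - (a_inf - a0) * np.exp(-duration / tau_a)
        r0 = r_inf - (r_inf - r0) * np.exp(-duration / tau_r)
        t_seg_start = t_seg_end
        idx0 = idx1
    if idx0 < len(times):  # samples at/after the last boundary
        a_out[idx0:] = a0
        r_out[idx0:] = r0
        v_out[idx0:] = protocol.segments[-1][1]

    currents = params.g * a_out * r_out * (v_out - EK)
    return CurrentTrace(times, currents, v_out,
                        metadata={"method": "analytic", "dt": dt, "EK": EK})


def _rhs_factory(params: KineticParameters, v_of_t):
    def rhs(t, y):
        a, r = y
        k1, k2, k3, k4 = transition_rates(params, v_of_t(t))
        return [k1 * (1.0 - a) - k2 * a, k4 * (1.0 - r) - k3 * r]
    return rhs


def _clip_gates(a, r):
    worst = max(np.max(a) - 1.0, -np.min(a), np.max(r) - 1.0, -np.min(r))
    if worst > 1e-6:
        warnings.warn(f"gate excursion outside [0,1] by {worst:.3g}; clipped",
                      RuntimeWarning)
    return np.clip(a, 0.0, 1.0), np.clip(r, 0.0, 1.0)


def simulate_ode(params: KineticParameters,
                 protocol,
                 cond: IonicConditions | None = None,
                 settings: SolverSettings | None = None,
                 initial_state: GateState | None = None) -> CurrentTrace:
    """Numerical integration of the gate ODEs under any protocol."""
    settings = settings or SolverSettings()
    cond = cond or IonicConditions()
    EK = reversal_potential(cond)

    if isinstance(protocol, StepProtocol):
        if initial_state is None:
            initial_state = default_initial_state(params,
                                                  protocol.segments[0][1])
        times = _sample_times(protocol.total_duration, settings.dt)
        a_out = np.empty_like(times)
        r_out = np.empty_like(times)
        y0 = [initial_state.a, initial_state.r]
        t_start = 0.0
        idx0 = 0
        for seg_index, (duration, v0, v1) in enumerate(protocol.segments):
            t_end = t_start + duration
            idx1 = int(np.searchsorted(times, t_end - 1e-12, side="left"))
            if v0 == v1:
                v_of_t = (lambda v: (lambda t: v))(v0)
            else:
                slope = (v1 - v0) / duration
                v_of_t = (lambda v0_, s_, ts_: (
                    lambda t: v0_ + s_ * (t - ts_)))(v0, slope, t_start)
            t_eval = times[idx0:idx1]
            rhs = _rhs_factory(params, v_of_t)
            if len(t_eval):
                sol = solve_ivp(
                    rhs, (t_start, t_end), y0, method="LSODA",
                    t_eval=t_eval, rtol=settings.rel_tol,
                    atol=settings.abs_tol,
                    max_step=settings.max_step or np.inf)
                if not sol.success:
                    raise IntegrationError(
                        f"solver failed in segment {seg_index}: {sol.message}")
                a_out[idx0:idx1] = sol.y[0]
                r_out[idx0:idx1] = sol.y[1]
                y0 = [sol.y[0, -1], sol.y[1, -1]]
                t_chain = float(sol.t[-1])
            else:
                t_chain = t_start
            if t_chain < t_end:  # carry the state exactly to the boundary
                sol_end = solve_ivp(
                    rhs, (t_chain, t_end), y0, method="LSODA",
                    rtol=settings.rel_tol, atol=settings.abs_tol,
                    max_step=settings.max_step or np.inf)
                if not sol_end.success:
                    raise IntegrationError(
                        f"solver failed in segment {seg_index}: "
                        f"{sol_end.message}")
                y0 = [sol_end.y[0, -1], sol_end.y[1, -1]]
            t_start = t_end
            idx0 = idx1
        if idx0 < len(times):
            a_out[idx0:], r_out[idx0:] = y0[0], y0[1]
        v_out = protocol.voltage_at(times)
    elif isinstance(protocol, SampledProtocol):
        if initial_state is None:
            initial_state = default_initial_state(params,
                                                  protocol.voltages[0])
        times = protocol.times - protocol.times[0]
        v_of_t = lambda t: np.interp(t, times, protocol.voltages)
        max_step = settings.max_step or protocol.dt
        sol = solve_ivp(
            _rhs_factory(params, v_of_t), (times[0], times[-1]),
            [initial_state.a, initial_state.r], method="LSODA",
            t_eval=times, rtol=settings.rel_tol, atol=settings.abs_tol,
            max_step=max_step)
        if not sol.success:
            raise IntegrationError(f"solver failed: {sol.message}")
        a_out, r_out = sol.y[0], sol.y[1]
        v_out = protocol.voltages.copy()
    else:
        raise TypeError(f"unsupported protocol type {type(protocol)!r}")

    a_out, r_out = _clip_gates(a_out, r_out)
    currents = params.g * a_out * r_out * (v_out - EK)
    return CurrentTrace(times, currents, v_out,
                        metadata={"method": "ode", "EK": EK})
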