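"""Core algebra of the two-gate Hodgkin-Huxley hERG (Kv11.1) model.

The rapid delayed-rectifier current is modelled as

    I_Kr = g_Kr * a * r * (V - E_K),

with an activation gate ``a`` (slow) and an inactivation gate ``r`` (fast),
each relaxing exponentially toward a voltage-dependent steady state.  The
four voltage-dependent transition rates take the thermodynamic form
``k = A * exp(B * V)``:

    k1 = p1 * exp( p2 * V)      (activation)
    k2 = p3 * exp(-p4 * V)      (deactivation)
    k3 = p5 * exp( p6 * V)      (inactivation)
    k4 = p7 * exp(-p8 * V)      (recovery from inactivation)

All nine parameters {g_Kr, p1..p8} are strictly positive; the signs of the
voltage dependence are carried by the rate law, not by the parameters.

Units: time ms, voltage mV, rates 1/ms, prefactors 1/ms, voltage
sensitivities 1/mV, conductance in arbitrary current units per mV.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.special import expit

from .constants import CONSTANTS, celsius_to_kelvin

__all__ = [
    "KineticParameters",
    "RateCoefficients",
    "IonicConditions",
    "GateState",
    "transition_rates",
    "steady_states",
    "time_constants",
    "reversal_potential",
    "current",
    "half_activation_voltage",
    "tau_peak",
    "open_probability_curve",
]

# Exponent magnitude above which exp() is clamped. Physiological voltages
# never approach this; only extreme parameter proposals from optimizers do.
_EXP_CLAMP = 700.0

PARAMETER_NAMES = ("g", "p1", "p2", "p3", "p4", "p5", "p6", "p7", "p8")

# Indices (into the 9-vector) of rate prefactors (A-type) and voltage
# sensitivities (B-type).
A_TYPE_INDICES = (1, 3, 5, 7)
B_TYPE_INDICES = (2, 4, 6, 8)


class InvalidParameterError(ValueError):
    """Raised when kinetic parameters violate their invariants."""


class DegenerateParametersError(ValueError):
    """Raised when a closed-form derived quantity does not exist."""


def _safe_exp(x):
    """exp() with the exponent clamped to avoid overflow.

    Clamping only triggers for parameter proposals far outside the
    physical regime; a warning is emitted so silent saturation is visible.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > _EXP_CLAMP):
        warnings.warn(
            "exponent clamped to +/-700 in rate evaluation", RuntimeWarning,
            stacklevel=3,
        )
        x = np.clip(x, -_EXP_CLAMP, _EXP_CLAMP)
    return np.exp(x)


@dataclass(frozen=True)
class KineticParameters:
    """The nine positive model parameters at one temperature.

    ``g`` is the maximal conductance; p1, p3, p5, p7 are rate prefactors
    (1/ms); p2, p4, p6, p8 are voltage sensitivities (1/mV, stored positive
    with signs applied by the rate law).
    """

    g: float
    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    p7: float
    p8: float
    temperature_C: float | None = None

    def __post_init__(self):
        vec = self.as_vector()
        if not np.all(np.isfinite(vec)):
            raise InvalidParameterError("parameters must be finite")
        if np.any(vec <= 0):
            raise InvalidParameterError("all nine parameters must be > 0")

    def as_vector(self) -> np.ndarray:
        """Parameters as a 9-vector in the order (g, p1, ..., p8)."""
        return np.array([getattr(self, n) for n in PARAMETER_NAMES])

    def log_vector(self) -> np.ndarray:
        return np.log(self.as_vector())

    @classmethod
    def from_vector(cls, vec: Iterable[float],
                    temperature_C: float | None = None) -> "KineticParameters":
        vec = np.asarray(list(vec), dtype=float)
        if vec.shape != (9,):
            raise InvalidParameterError("expected 9 parameters (g, p1..p8)")
        return cls(*vec, temperature_C=temperature_C)

    @classmethod
    def from_log_vector(cls, phi: Iterable[float],
                        temperature_C: float | None = None) -> "KineticParameters":
        return cls.from_vector(np.exp(np.asarray(list(phi), dtype=float)),
                               temperature_C=temperature_C)

    def to_json(self, path=None) -> str:
        d = {n: float(getattr(self, n)) for n in PARAMETER_NAMES}
        d["temperature_C"] = self.temperature_C
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as f:
                f.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "KineticParameters":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as f:
                d = json.load(f)
        temp = d.pop("temperature_C", None)
        return cls(**{n: d[n] for n in PARAMETER_NAMES}, temperature_C=temp)


@dataclass(frozen=True)
class RateCoefficients:
    """A single transition rate k = A*exp(B*V); B is signed."""

    A: float
    B: float

    def __post_init__(self):
        if not (self.A > 0 and math.isfinite(self.A) and math.isfinite(self.B)):
            raise InvalidParameterError("require A > 0 and finite A, B")

    def __call__(self, V):
        return self.A * _safe_exp(self.B * np.asarray(V, dtype=float))


@dataclass(frozen=True)
class IonicConditions:
    """Ionic conditions that set the Nernst potential.

    Ko/Ki are extra-/intracellular K+ concentrations (mM), T is absolute
    temperature (K), z the ion valency (1 for K+).
    """

    Ko: float = 4.0
    Ki: float = 110.0
    T: float = celsius_to_kelvin(25.0)
    z: int = 1

    def __post_init__(self):
        if not (self.Ko > 0 and self.Ki > 0 and self.T > 0):
            raise InvalidParameterError("require Ko, Ki, T > 0")

    @classmethod
    def at_celsius(cls, t_celsius: float, Ko: float = 4.0,
                   Ki: float = 110.0) -> "IonicConditions":
        return cls(Ko=Ko, Ki=Ki, T=celsius_to_kelvin(t_celsius))


@dataclass(frozen=True)
class GateState:
    """Open fractions of the activation (a) and inactivation (r) gates."""

    a: float
    r: float

    def __post_init__(self):
        if not (0.0 <= self.a <= 1.0 and 0.0 <= self.r <= 1.0):
            raise InvalidParameterError("gate fractions must lie in [0, 1]")


def _check_voltage(V):
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise InvalidParameterError("voltage must be finite")
    return V


def transition_rates(params: KineticParameters, V):
    """The four transition rates (k1, k2, k3, k4) at voltage V (mV).

    Vectorized over V. Rates are strictly positive (1/ms).
    """
    V = _check_voltage(V)
    k1 = params.p1 * _safe_exp(params.p2 * V)
    k2 = params.p3 * _safe_exp(-params.p4 * V)
    k3 = params.p5 * _safe_exp(params.p6 * V)
    k4 = params.p7 * _safe_exp(-params.p8 * V)
    return k1, k2, k3, k4


def steady_states(params: KineticParameters, V):
    """Steady-state gate open fractions (a_inf, r_inf) at voltage V.

    Computed in log space (logistic form), so no overflow is possible:
    a_inf = 1/(1 + k2/k1) = expit(ln k1 - ln k2), similarly for r_inf.
    """
    V = _check_voltage(V)
    a_inf = expit(math.log(params.p1 / params.p3) + (params.p2 + params.p4) * V)
    r_inf = expit(math.log(params.p7 / params.p5) - (params.p6 + params.p8) * V)
    return a_inf, r_inf


def time_constants(params: KineticParameters, V):
    """Gate relaxation time constants (tau_a, tau_r) in ms at voltage V."""
    k1, k2, k3, k4 = transition_rates(params, V)
    return 1.0 / (k1 + k2), 1.0 / (k3 + k4)


def reversal_potential(cond: IonicConditions) -> float:
    """Nernst reversal potential E_K in mV."""
    volts = (CONSTANTS.R * cond.T) / (cond.z * CONSTANTS.F) * math.log(
        cond.Ko / cond.Ki)
    return volts * 1000.0


def current(params: KineticParameters, state: GateState, V, EK):
    """Ohmic current I_Kr = g * a * r * (V - E_K)."""
    return params.g * state.a * state.r * (np.asarray(V, dtype=float) - EK)


def half_activation_voltage(params: KineticParameters) -> float:
    """Voltage V_1/2 (mV) at which a_inf = 1/2.

    Closed form: a_inf = 1/2 iff k1 = k2, giving
    V_1/2 = ln(p3/p1) / (p2 + p4).
    """
    denom = params.p2 + params.p4
    if denom <= 0:
        raise DegenerateParametersError(
            "a_inf is constant in V when p2 + p4 = 0")
    v_half = math.log(params.p3 / params.p1) / denom
    if not math.isfinite(v_half):
        raise DegenerateParametersError(
            "vanishing voltage sensitivities: no finite half-activation")
    return v_half


def tau_peak(params: KineticParameters, gate: str = "activation"):
    """Location and height of the interior maximum of a gate time constant.

    tau = 1/(A1*exp(B1*V) + A2*exp(-B2*V)) is maximal where the denominator
    is minimal:  V* = ln(A2*B2/(A1*B1)) / (B1 + B2).

    Returns (V* in mV, tau_max in ms).
    """
    if gate == "activation":
        A1, B1, A2, B2 = params.p1, params.p2, params.p3, params.p4
    elif gate == "inactivation":
        A1, B1, A2, B2 = params.p5, params.p6, params.p7, params.p8
    else:
        raise ValueError("gate must be 'activation' or 'inactivation'")
    if B1 <= 0 or B2 <= 0:
        raise DegenerateParametersError(
            "no interior maximum when a voltage sensitivity is zero")
    v_star = math.log((A2 * B2) / (A1 * B1)) / (B1 + B2)
    tau_a, tau_r = time_constants(params, v_star)
    tau_max = tau_a if gate == "activation" else tau_r
    return v_star, float(tau_max)


def open_probability_curve(params: KineticParameters, voltages):
    """Steady-state open probability a_inf * r_inf on a voltage grid."""
    a_inf, r_inf = steady_states(params, voltages)
    return a_inf * r_inf
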