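"""Physical constants and unit helpers.

CODATA 2018 values. The package works in the electrophysiology convention:
time in milliseconds, voltage in millivolts, rates in 1/ms, temperature in
kelvin internally (Celsius at user-facing interfaces).
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA 2018 physical constants (SI units)."""

    R: float = 8.31446261815324  # molar gas constant, J / (mol K)
    F: float = 96485.33212331001  # Faraday constant, C / mol
    kB: float = 1.380649e-23  # Boltzmann constant, J / K (exact)
    h: float = 6.62607015e-34  # Planck constant, J s (exact)


CONSTANTS = PhysicalConstants()

ZERO_CELSIUS_K = 273.15


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + ZERO_CELSIUS_K


def kelvin_to_celsius(t_kelvin: float) -> float:
    return t_kelvin - ZERO_CELSIUS_K
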