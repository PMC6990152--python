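"""Voltage-clamp protocols: data model, text I/O, built-ins, I-V extraction.

Two protocol representations are supported:

* :class:`StepProtocol` — an ordered list of segments ``(duration,
  v_start, v_end)``; equal start/end voltage encodes a constant step,
  unequal a linear ramp.  Segments are half-open ``[t_start, t_end)`` so
  the voltage at a step boundary is the *new* segment's voltage.
* :class:`SampledProtocol` — a uniformly sampled ``(t, V)`` waveform, used
  for action-potential-like commands.

The built-in library includes a fixture staircase (same ~15 s duration,
-120..+60 mV range and leading +40 -> -120 mV tail step as the
information-rich calibration staircase used for hERG characterisation;
the exact published ladder can be loaded from file instead), I-V step
families, and action-potential-like waveforms at 0.5/1/2 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "StepProtocol",
    "SampledProtocol",
    "IVCurve",
    "ProtocolFormatError",
    "read_protocol",
    "write_protocol",
    "builtin_protocol",
    "BUILTIN_PROTOCOLS",
    "extract_iv",
]


class ProtocolFormatError(ValueError):
    """Raised for malformed protocol files."""


@dataclass(frozen=True)
class StepProtocol:
    """Piecewise step/ramp command voltage.

    ``segments`` is a tuple of (duration_ms, v_start_mV, v_end_mV).
    """

    segments: tuple

    def __post_init__(self):
        segs = tuple((float(d), float(v0), float(v1))
                     for d, v0, v1 in self.segments)
        if len(segs) == 0:
            raise ProtocolFormatError("protocol needs at least one segment")
        if any(d <= 0 or not math.isfinite(d) for d, _, _ in segs):
            raise ProtocolFormatError("segment durations must be positive")
        object.__setattr__(self, "segments", segs)

    @classmethod
    def from_steps(cls, steps) -> "StepProtocol":
        """Build from (duration, voltage) pairs (constant steps only)."""
        return cls(tuple((d, v, v) for d, v in steps))

    @property
    def total_duration(self) -> float:
        return sum(d for d, _, _ in self.segments)

    @property
    def is_step_only(self) -> bool:
        return all(v0 == v1 for _, v0, v1 in self.segments)

    @property
    def boundaries(self) -> np.ndarray:
        """Segment start times plus the final end time."""
        return np.concatenate(
            [[0.0], np.cumsum([d for d, _, _ in self.segments])])

    def voltage_at(self, t):
        """Command voltage at time t (ms); right-continuous at boundaries."""
        t = np.asarray(t, dtype=float)
        b = self.boundaries
        idx = np.clip(np.searchsorted(b, t, side="right") - 1, 0,
                      len(self.segments) - 1)
        durs = np.array([s[0] for s in self.segments])
        v0 = np.array([s[1] for s in self.segments])
        v1 = np.array([s[2] for s in self.segments])
        frac = np.clip((t - b[idx]) / durs[idx], 0.0, 1.0)
        return v0[idx] + frac * (v1[idx] - v0[idx])


@dataclass(frozen=True)
class SampledProtocol:
    """Uniformly sampled command voltage waveform."""

    times: np.ndarray
    voltages: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.voltages, dtype=float)
        if t.shape != v.shape or t.ndim != 1 or len(t) < 2:
            raise ProtocolFormatError("times/voltages must be equal-length 1-D")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ProtocolFormatError("times must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ProtocolFormatError("sampling interval must be uniform")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "voltages", v)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def total_duration(self) -> float:
        return float(self.times[-1] - self.times[0] + self.dt)

    def voltage_at(self, t):
        return np.interp(np.asarray(t, dtype=float), self.times, self.voltages)


@dataclass(frozen=True)
class IVCurve:
    """Current-voltage relation: (test voltage, summary current) pairs."""

    voltages: np.ndarray
    currents: np.ndarray
    rule: str = "peak"

    def __post_init__(self):
        v = np.asarray(self.voltages, dtype=float)
        i = np.asarray(self.currents, dtype=float)
        if v.shape != i.shape or v.ndim != 1:
            raise ValueError("voltages/currents must be equal-length 1-D")
        order = np.argsort(v)
        v, i = v[order], i[order]
        if len(np.unique(v)) != len(v):
            raise ValueError("test voltages must be unique")
        object.__setattr__(self, "voltages", v)
        object.__setattr__(self, "currents", i)

    def to_csv(self, path):
        with open(path, "w") as f:
            f.write("v_mV,summary_current\n")
            for v, i in zip(self.voltages, self.currents):
                f.write(f"{v:.17g},{i:.17g}\n")

    @classmethod
    def from_csv(cls, path, rule="peak"):
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(data[:, 0], data[:, 1], rule=rule)


# ---------------------------------------------------------------------------
# File I/O

def write_protocol(protocol, path):
    path = Path(path)
    if isinstance(protocol, StepProtocol):
        with open(path, "w") as f:
            f.write("# duration_ms v_start_mV v_end_mV\n")
            for d, v0, v1 in protocol.segments:
                f.write(f"{d:.17g} {v0:.17g} {v1:.17g}\n")
    elif isinstance(protocol, SampledProtocol):
        with open(path, "w") as f:
            f.write("t_ms,v_mV\n")
            for t, v in zip(protocol.times, protocol.voltages):
                f.write(f"{t:.17g},{v:.17g}\n")
    else:
        raise TypeError(f"unsupported protocol type {type(protocol)!r}")


def read_protocol(path):
    """Read a step-protocol text file or a sampled-waveform CSV."""
    path = Path(path)
    with open(path) as f:
        lines = f.readlines()
    stripped = [(n + 1, ln.strip()) for n, ln in enumerate(lines)]
    content = [(n, ln) for n, ln in stripped
               if ln and not ln.startswith("#")]
    if not content:
        raise ProtocolFormatError(f"{path}: no protocol data found")
    first = content[0][1]
    if "," in first:  # sampled CSV, possibly with a header line
        rows = []
        for n, ln in content:
            parts = [p.strip() for p in ln.split(",")]
            if len(parts) != 2:
                raise ProtocolFormatError(f"{path}:{n}: expected 2 columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if n == content[0][0]:  # header
                    continue
                raise ProtocolFormatError(
                    f"{path}:{n}: could not parse '{ln}'") from None
        t = np.array([r[0] for r in rows])
        v = np.array([r[1] for r in rows])
        if np.any(np.diff(t) <= 0):
            raise ProtocolFormatError(f"{path}: times must be increasing")
        return SampledProtocol(t, v)
    segments = []
    for n, ln in content:
        parts = ln.split()
        if len(parts) != 3:
            raise ProtocolFormatError(
                f"{path}:{n}: expected 'duration v_start v_end'")
        try:
            segments.append(tuple(float(p) for p in parts))
        except ValueError:
            raise ProtocolFormatError(
                f"{path}:{n}: could not parse '{ln}'") from None
    return StepProtocol(tuple(segments))


# ---------------------------------------------------------------------------
# Built-in protocols

def staircase_fixture() -> StepProtocol:
    """Fixture calibration staircase (~15 s, -120..+60 mV).

    Layout: a leading +40 -> -120 mV activation/tail step (used by the
    tail-extrapolation conductance estimate), a return to holding, an
    ascending then descending ladder of 500 ms steps alternating with
    500 ms drops 60 mV below each rung, and a closing -120 mV step.
    This is the package's own documented ladder with the same duration,
    voltage range and leading tail step as the published calibration
    staircase (whose exact rungs are not reproduced here).
    """
    steps = [(250.0, -80.0), (500.0, 40.0), (500.0, -120.0), (1000.0, -80.0)]
    for v_hi in (-60.0, -40.0, -20.0, 0.0, 20.0, 40.0, 60.0):  # ascending
        steps += [(500.0, v_hi), (500.0, v_hi - 60.0)]
    for v_hi in (40.0, 20.0, 0.0, -20.0, -40.0):  # descending
        steps += [(500.0, v_hi), (500.0, v_hi - 60.0)]
    steps += [(500.0, -120.0), (250.0, -80.0)]
    return StepProtocol.from_steps(steps)


def activation_iv(v_start=-60.0, v_stop=40.0, dv=10.0, holding=-80.0,
                  t_hold=2000.0, t_test=5000.0, t_tail=3000.0,
                  v_tail=-40.0):
    """Activation I-V family: hold, depolarising test step, fixed tail.

    Returns a list of StepProtocol, one sweep per test voltage, plus the
    list of test voltages (as the ``test_voltages`` attribute pattern is
    avoided, the caller receives a (sweeps, voltages) tuple).
    """
    voltages = np.arange(v_start, v_stop + 0.5 * dv, dv)
    sweeps = [StepProtocol.from_steps(
        [(t_hold, holding), (t_test, v), (t_tail, v_tail), (500.0, holding)])
        for v in voltages]
    return sweeps, voltages


def inactivation_iv(v_start=-120.0, v_stop=0.0, dv=10.0, holding=-80.0,
                    t_hold=1000.0, t_depol=500.0, v_depol=40.0,
                    t_test=50.0, t_tail=500.0):
    """Steady-state inactivation I-V family: depolarise then repolarise."""
    voltages = np.arange(v_start, v_stop + 0.5 * dv, dv)
    sweeps = [StepProtocol.from_steps(
        [(t_hold, holding), (t_depol, v_depol), (t_test, v),
         (t_tail, holding)])
        for v in voltages]
    return sweeps, voltages


def ap_like(frequency_hz=1.0, n_beats=1, dt=1.0, holding=-80.0,
            peak=40.0, resting=-85.0) -> SampledProtocol:
    """Action-potential-like sampled waveform repeated at a beat frequency.

    Each beat: 2 ms upstroke from holding to the peak, a smooth
    repolarisation over ~300 ms back to the resting potential, then rest
    until the next beat.
    """
    beat_ms = 1000.0 / frequency_hz
    t = np.arange(0.0, beat_ms, dt)
    v = np.full_like(t, resting)
    up = t < 2.0
    v[up] = holding + (peak - holding) * (t[up] / 2.0)
    repol = (t >= 2.0) & (t < 302.0)
    s = (t[repol] - 2.0) / 300.0
    # smooth plateau-then-fall repolarisation
    v[repol] = resting + (peak - resting) * (1.0 - s) ** 2 * (1.0 + 1.2 * s)
    waveform = np.tile(v, n_beats)
    times = np.arange(len(waveform)) * dt
    return SampledProtocol(times, waveform)


BUILTIN_PROTOCOLS = {
    "staircase-fixture": staircase_fixture,
    "activation-iv": activation_iv,
    "inactivation-iv": inactivation_iv,
    "ap-0.5hz": lambda **kw: ap_like(frequency_hz=0.5, **kw),
    "ap-1hz": lambda **kw: ap_like(frequency_hz=1.0, **kw),
    "ap-2hz": lambda **kw: ap_like(frequency_hz=2.0, **kw),
}


def builtin_protocol(name, **options):
    """Look up a built-in protocol by name.

    ``activation-iv`` / ``inactivation-iv`` return ``(sweeps, voltages)``;
    the others return a single protocol object.
    """
    try:
        factory = BUILTIN_PROTOCOLS[name]
    except KeyError:
        raise KeyError(
            f"unknown protocol {name!r}; valid names: "
            f"{sorted(BUILTIN_PROTOCOLS)}") from None
    return factory(**options)


# ---------------------------------------------------------------------------
# Summary statistics

def extract_iv(traces, voltages, window, rule="peak") -> IVCurve:
    """Extract an I-V relation from one trace per test voltage.

    window : (t0, t1) in ms; the summary is computed on samples with
        t0 <= t < t1.
    rule : 'peak' takes the signed value of largest magnitude in the
        window (peak current for the inactivation I-V, peak tail current
        for the activation I-V when the window covers the tail step).
    """
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("empty summary window")
    if len(traces) != len(voltages):
        raise ValueError("need exactly one trace per test voltage")
    summaries = []
    for trace in traces:
        mask = (trace.times >= t0) & (trace.times < t1)
        if not np.any(mask):
            raise ValueError(f"window ({t0}, {t1}) outside trace")
        seg = trace.currents[mask]
        if rule in ("peak", "peak-tail"):
            summaries.append(seg[np.argmax(np.abs(seg))])
        else:
            raise ValueError(f"unknown summary rule {rule!r}")
    return IVCurve(np.asarray(voltages, float), np.array(summaries), rule=rule)
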