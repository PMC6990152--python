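"""Synthetic multi-well, multi-temperature voltage-clamp datasets.

The generator mirrors the statistical structure the inference assumes:

* per-well log-parameters drawn from a multivariate normal,
  ``phi_j ~ N(mu, Sigma)`` (conductance included as one coordinate, giving
  it an independent lognormal spread),
* additive i.i.d. Gaussian current noise on each trace,
* a population mean ``mu(T)`` that moves with temperature according to a
  Generalized Eyring law per transition rate, so that temperature-model
  fitting is exactly recoverable on noiseless data.

Defaults emulate the study conditions of a multi-well patch-clamp
temperature experiment: five temperatures (25, 27, 30, 33, 37 C),
[K+]o/[K+]i = 4/110 mM, current noise with a standard deviation of 5% of
each well's peak current, and hERG-like kinetic magnitudes (activation time
constants of seconds and inactivation time constants of milliseconds at
25 C; the activation rates much more temperature sensitive than the
inactivation rates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import celsius_to_kelvin
from .model import KineticParameters, IonicConditions
from .protocols import StepProtocol, read_protocol, write_protocol
from .simulate import CurrentTrace, simulate_step_analytic, simulate_ode

__all__ = [
    "HierarchicalTruth",
    "TemperatureTruth",
    "SyntheticWell",
    "SyntheticDataset",
    "CovarianceError",
    "DEFAULT_TEMPERATURES_C",
    "default_temperature_truth",
    "parameters_at_temperature",
    "hierarchical_truth_at",
    "sample_well_parameters",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
]

DEFAULT_TEMPERATURES_C = (25.0, 27.0, 30.0, 33.0, 37.0)

# Default well-to-well spread of the log-parameters (diagonal SDs): modest
# kinetic variability, broader conductance variability (expression levels
# vary much more between cells than kinetics do).
DEFAULT_LOG_SD = np.array(
    [0.20, 0.10, 0.05, 0.10, 0.05, 0.10, 0.05, 0.10, 0.05])

DEFAULT_NOISE_FRACTION = 0.05  # noise SD as a fraction of peak |current|


class CovarianceError(ValueError):
    pass


def _check_covariance(sigma: np.ndarray) -> np.ndarray:
    sigma = np.asarray(sigma, dtype=float)
    if sigma.shape != (9, 9):
        raise CovarianceError("Sigma must be 9x9")
    if not np.allclose(sigma, sigma.T, atol=1e-12):
        raise CovarianceError("Sigma must be symmetric")
    eigvals = np.linalg.eigvalsh(sigma)
    if np.min(eigvals) < -1e-10 * max(1.0, np.max(np.abs(eigvals))):
        raise CovarianceError("Sigma must be positive semi-definite")
    return sigma


@dataclass(frozen=True)
class HierarchicalTruth:
    """Ground truth of the population model at one temperature.

    mu/Sigma parameterise the multivariate normal of the 9 log-parameters
    (order g, p1..p8).  Noise is specified either as an absolute current
    SD (``noise_sd``) or as a fraction of each well's peak current
    (``noise_fraction``); the fractional form is the default.
    """

    mu: np.ndarray
    sigma: np.ndarray
    temperature_C: float
    noise_sd: float | None = None
    noise_fraction: float = DEFAULT_NOISE_FRACTION

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float)
        if mu.shape != (9,):
            raise ValueError("mu must have 9 entries")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", _check_covariance(self.sigma))
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")

    @property
    def mean_parameters(self) -> KineticParameters:
        return KineticParameters.from_log_vector(
            self.mu, temperature_C=self.temperature_C)


# Transition rate i uses parameter pair (A, B) at these vector positions.
RATE_PARAM_INDICES = {1: (1, 2), 2: (3, 4), 3: (5, 6), 4: (7, 8)}


@dataclass(frozen=True)
class TemperatureTruth:
    """Generalized Eyring coefficients per rate, defining mu(T).

    Arrays are ordered (k1, k2, k3, k4).  ``a_ge`` in 1/(ms K), ``b_ge``
    in K, ``c_ge`` in K/mV, ``d_ge`` in 1/mV.  The conductance mean is
    temperature independent (its distribution is lognormal per well).
    """

    a_ge: np.ndarray
    b_ge: np.ndarray
    c_ge: np.ndarray
    d_ge: np.ndarray
    g_mean: float = 0.1
    log_sd: np.ndarray = field(
        default_factory=lambda: DEFAULT_LOG_SD.copy())
    noise_fraction: float = DEFAULT_NOISE_FRACTION

    def __post_init__(self):
        for name in ("a_ge", "b_ge", "c_ge", "d_ge"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (4,):
                raise ValueError(f"{name} must have 4 entries (k1..k4)")
            object.__setattr__(self, name, arr)
        if np.any(self.a_ge <= 0):
            raise ValueError("a_ge must be positive")
        if self.g_mean <= 0:
            raise ValueError("g_mean must be positive")
        object.__setattr__(self, "log_sd",
                           np.asarray(self.log_sd, dtype=float))

    def to_json(self, path=None) -> str:
        d = {k: np.asarray(getattr(self, k)).tolist()
             for k in ("a_ge", "b_ge", "c_ge", "d_ge", "log_sd")}
        d["g_mean"] = self.g_mean
        d["noise_fraction"] = self.noise_fraction
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source) -> "TemperatureTruth":
        text = Path(source).read_text() if not str(source).lstrip().startswith(
            "{") else str(source)
        d = json.loads(text)
        return cls(**d)


def parameters_at_temperature(truth: TemperatureTruth,
                              T_kelvin: float) -> KineticParameters:
    """Population-mean kinetic parameters at absolute temperature T.

    A-type prefactors follow A = a_GE * T * exp(-b_GE / T); B-type
    sensitivities follow B = c_GE / T + d_GE (stored unsigned; the rate
    law applies the signs).
    """
    if T_kelvin <= 0:
        raise ValueError("T must be positive (kelvin)")
    vec = np.empty(9)
    vec[0] = truth.g_mean
    for rate, (ia, ib) in RATE_PARAM_INDICES.items():
        i = rate - 1
        vec[ia] = truth.a_ge[i] * T_kelvin * np.exp(-truth.b_ge[i] / T_kelvin)
        vec[ib] = truth.c_ge[i] / T_kelvin + truth.d_ge[i]
    return KineticParameters.from_vector(
        vec, temperature_C=T_kelvin - 273.15)


def _ge_from_anchor(A_anchor, fold_per_10K, B_anchor, c_ge,
                    T_anchor=celsius_to_kelvin(25.0)):
    """Back out (a_GE, b_GE, c_GE, d_GE) from values at an anchor temperature.

    ``fold_per_10K`` is the factor by which the prefactor grows from
    T_anchor to T_anchor + 10 K.
    """
    T2 = T_anchor + 10.0
    b_ge = (np.log(fold_per_10K) - np.log(T2 / T_anchor)) / (
        1.0 / T_anchor - 1.0 / T2)
    a_ge = A_anchor / (T_anchor * np.exp(-b_ge / T_anchor))
    d_ge = B_anchor - c_ge / T_anchor
    return a_ge, b_ge, c_ge, d_ge


def default_temperature_truth() -> TemperatureTruth:
    """Fixture ground truth with hERG-like magnitudes.

    Anchored at 25 C to representative room-temperature hERG model
    magnitudes (activation tau of seconds, inactivation tau of
    milliseconds), with the activation rates (k1, k2) considerably more
    temperature sensitive than the inactivation rates (k3, k4) and nonzero
    1/T dependence of every voltage sensitivity.  These are documented
    fixture values, not fitted estimates.
    """
    # (A at 25 C [1/ms], fold per +10 K, B at 25 C [1/mV], c_GE [K/mV])
    anchors = [
        (2.26e-4, 8.0, 0.0699, 40.0),   # k1 activation
        (3.45e-5, 5.0, 0.05462, 25.0),  # k2 deactivation
        (0.0873, 3.2, 0.00891, 3.0),    # k3 inactivation
        (5.15e-3, 2.6, 0.03158, 15.0),  # k4 recovery
    ]
    a, b, c, d = zip(*(_ge_from_anchor(*row) for row in anchors))
    return TemperatureTruth(np.array(a), np.array(b), np.array(c),
                            np.array(d))


def hierarchical_truth_at(truth: TemperatureTruth, temperature_C: float,
                          log_sd: np.ndarray | None = None,
                          noise_fraction: float | None = None,
                          noise_sd: float | None = None) -> HierarchicalTruth:
    """Population truth (mu, Sigma) at one temperature from an Eyring truth."""
    params = parameters_at_temperature(truth,
                                       celsius_to_kelvin(temperature_C))
    sd = truth.log_sd if log_sd is None else np.asarray(log_sd, dtype=float)
    frac = truth.noise_fraction if noise_fraction is None else noise_fraction
    return HierarchicalTruth(
        mu=params.log_vector(), sigma=np.diag(sd ** 2),
        temperature_C=temperature_C, noise_sd=noise_sd,
        noise_fraction=frac)


def sample_well_parameters(truth: HierarchicalTruth, n_wells: int,
                           seed) -> list[KineticParameters]:
    """Draw per-well parameters exp(phi_j), phi_j ~ N(mu, Sigma)."""
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    rng = np.random.default_rng(seed)
    phis = rng.multivariate_normal(truth.mu, truth.sigma, size=n_wells,
                                   method="eigh")
    return [KineticParameters.from_log_vector(
        phi, temperature_C=truth.temperature_C) for phi in phis]


@dataclass
class SyntheticWell:
    well_id: str
    params: KineticParameters
    noise_sd: float
    trace: CurrentTrace


@dataclass
class SyntheticDataset:
    truth: HierarchicalTruth
    protocol: StepProtocol
    wells: list
    seed: int

    @property
    def traces(self):
        return [w.trace for w in self.wells]


def generate_dataset(truth: HierarchicalTruth, protocol, n_wells: int,
                     seed, dt: float = 1.0, Ko: float = 4.0,
                     Ki: float = 110.0) -> SyntheticDataset:
    """Generate a multi-well dataset at the truth's temperature.

    Per well: draw parameters from the population, simulate the protocol
    (analytic path for step protocols, ODE otherwise), then add i.i.d.
    Gaussian noise with SD ``truth.noise_sd`` or, in fractional mode,
    ``truth.noise_fraction`` times the well's peak |current|.  Fully
    reproducible from (truth, seed).
    """
    rng = np.random.default_rng(seed)
    param_seed = int(rng.integers(2 ** 31))
    well_params = sample_well_parameters(truth, n_wells, param_seed)
    cond = IonicConditions(Ko=Ko, Ki=Ki,
                           T=celsius_to_kelvin(truth.temperature_C))
    wells = []
    for j, params in enumerate(well_params):
        try:
            if isinstance(protocol, StepProtocol) and protocol.is_step_only:
                trace = simulate_step_analytic(params, protocol, cond, dt=dt)
            else:
                trace = simulate_ode(params, protocol, cond)
        except Exception as exc:
            raise RuntimeError(f"simulation failed for well {j}") from exc
        if truth.noise_sd is not None:
            sd = truth.noise_sd
        else:
            sd = truth.noise_fraction * np.max(np.abs(trace.currents))
        if sd > 0:
            trace.currents = trace.currents + rng.normal(
                0.0, sd, size=trace.currents.shape)
        trace.metadata.update(well_id=f"well{j:03d}",
                              temperature_C=truth.temperature_C,
                              noise_sd=sd)
        wells.append(SyntheticWell(f"well{j:03d}", params, sd, trace))
    return SyntheticDataset(truth=truth, protocol=protocol, wells=wells,
                            seed=int(seed) if np.isscalar(seed) else seed)


def write_dataset(dataset: SyntheticDataset, directory):
    """Write a dataset as a directory of plain-text artifacts."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_protocol(dataset.protocol, directory / "protocol.txt")
    truth = {
        "mu": dataset.truth.mu.tolist(),
        "sigma": dataset.truth.sigma.tolist(),
        "temperature_C": dataset.truth.temperature_C,
        "noise_sd": dataset.truth.noise_sd,
        "noise_fraction": dataset.truth.noise_fraction,
        "seed": dataset.seed,
        "wells": {w.well_id: {"params": w.params.as_vector().tolist(),
                              "noise_sd": w.noise_sd}
                  for w in dataset.wells},
    }
    with open(directory / "truth.json", "w") as f:
        json.dump(truth, f, indent=2)
    for w in dataset.wells:
        w.trace.to_csv(directory / f"{w.well_id}.csv")


def read_dataset(directory) -> SyntheticDataset:
    directory = Path(directory)
    protocol = read_protocol(directory / "protocol.txt")
    with open(directory / "truth.json") as f:
        d = json.load(f)
    truth = HierarchicalTruth(
        mu=np.array(d["mu"]), sigma=np.array(d["sigma"]),
        temperature_C=d["temperature_C"], noise_sd=d["noise_sd"],
        noise_fraction=d["noise_fraction"])
    wells = []
    for well_id in sorted(d["wells"]):
        info = d["wells"][well_id]
        params = KineticParameters.from_vector(
            info["params"], temperature_C=d["temperature_C"])
        trace = CurrentTrace.from_csv(directory / f"{well_id}.csv")
        wells.append(SyntheticWell(well_id, params, info["noise_sd"], trace))
    return SyntheticDataset(truth=truth, protocol=protocol, wells=wells,
                            seed=d["seed"])
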