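"""Per-well posterior inference and hierarchical pooling at one temperature.

Model parameters are inferred in log space, ``phi = ln(theta)``, under a
uniform (box) prior, with an i.i.d. Gaussian noise model:

    I_data(t_k) = I_model(t_k; exp(phi)) + eps_k,   eps_k ~ N(0, sigma^2).

Three layers are provided:

* :func:`fit_well` — maximum a posteriori point estimation by multi-start
  bounded nonlinear least squares in log-parameter space.  The conductance
  enters the current linearly, so it is profiled analytically within each
  residual evaluation; the noise SD is profiled as the RMS residual.
* :func:`sample_well` — adaptive Metropolis MCMC on (phi, ln sigma),
  initialised at the point estimate, with Haario-style proposal-covariance
  adaptation and acceptance-rate targeting.
* :func:`fit_hierarchical` — pseudo-Metropolis-within-Gibbs for the
  population model phi_j ~ N(mu, Sigma): alternates drawing one phi_j from
  each well's pre-computed posterior sample pool with a conjugate
  normal-inverse-Wishart Gibbs update of (mu, Sigma).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .model import (A_TYPE_INDICES, B_TYPE_INDICES, IonicConditions,
                    KineticParameters, reversal_potential, steady_states,
                    transition_rates)
from .protocols import StepProtocol
from .simulate import CurrentTrace, simulate_ode, simulate_step_analytic

__all__ = [
    "ParameterBounds",
    "WellFit",
    "WellPosterior",
    "HierarchicalPosterior",
    "FitFailureError",
    "DivergentChainError",
    "log_likelihood",
    "log_posterior",
    "fit_well",
    "sample_well",
    "fit_hierarchical",
]

logger = logging.getLogger(__name__)


class FitFailureError(RuntimeError):
    pass


class DivergentChainError(RuntimeError):
    pass


def _default_bound_vectors():
    lower = np.empty(9)
    upper = np.empty(9)
    lower[0], upper[0] = 1e-5, 1e6  # conductance: broad
    for i in A_TYPE_INDICES:
        lower[i], upper[i] = 1e-7, 1e3
    for i in B_TYPE_INDICES:
        lower[i], upper[i] = 1e-7, 0.4
    return lower, upper


@dataclass(frozen=True)
class ParameterBounds:
    """Closed box prior bounds on theta (and hence on phi = ln theta).

    Defaults are broad, physically plausible ranges: prefactors in
    [1e-7, 1e3] / ms, voltage sensitivities in [1e-7, 0.4] / mV,
    conductance in [1e-5, 1e6].
    """

    lower: np.ndarray = field(default_factory=lambda: _default_bound_vectors()[0])
    upper: np.ndarray = field(default_factory=lambda: _default_bound_vectors()[1])

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        if lo.shape != (9,) or hi.shape != (9,):
            raise ValueError("bounds must be 9-vectors")
        if np.any(lo <= 0) or np.any(hi <= lo):
            raise ValueError("require 0 < lower < upper")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)

    @property
    def phi_lower(self) -> np.ndarray:
        return np.log(self.lower)

    @property
    def phi_upper(self) -> np.ndarray:
        return np.log(self.upper)

    def contains_phi(self, phi) -> bool:
        phi = np.asarray(phi, dtype=float)
        return bool(np.all(phi >= self.phi_lower)
                    and np.all(phi <= self.phi_upper))


# Default sampling box for optimisation starts: the physiologically
# plausible sub-region of the prior from which random restarts are drawn
# (prefactors spanning 1e-6..1 / ms, sensitivities 1e-3..0.2 / mV).
_START_LOWER = np.array([np.nan, 1e-6, 1e-3, 1e-6, 1e-3, 1e-6, 1e-3,
                         1e-6, 1e-3])
_START_UPPER = np.array([np.nan, 1.0, 0.2, 1.0, 0.2, 1.0, 0.2, 1.0, 0.2])


def _simulate_phi(phi, protocol, cond, dt, temperature_C=None):
    params = KineticParameters.from_log_vector(phi,
                                               temperature_C=temperature_C)
    if isinstance(protocol, StepProtocol) and protocol.is_step_only:
        return simulate_step_analytic(params, protocol, cond, dt=dt).currents
    return simulate_ode(params, protocol, cond).currents


def log_likelihood(phi, sigma, trace: CurrentTrace, protocol,
                   cond: IonicConditions) -> float:
    """i.i.d. Gaussian log-likelihood of the trace given (phi, sigma)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    y = trace.currents
    try:
        z = _simulate_phi(phi, protocol, cond, trace.dt)
    except Exception as exc:
        logger.debug("simulation failed in likelihood: %s", exc)
        return -np.inf
    if z.shape != y.shape or not np.all(np.isfinite(z)):
        return -np.inf
    n = len(y)
    ssr = float(np.sum((z - y) ** 2))
    return -0.5 * n * math.log(2.0 * math.pi * sigma ** 2) \
        - ssr / (2.0 * sigma ** 2)


def log_posterior(phi, sigma, trace, protocol, cond,
                  bounds: ParameterBounds | None = None) -> float:
    """Log posterior: likelihood plus the uniform box prior on phi.

    Bounds are closed intervals; boundary values are inside the prior.
    """
    bounds = bounds or ParameterBounds()
    if not bounds.contains_phi(phi):
        return -np.inf
    return log_likelihood(phi, sigma, trace, protocol, cond)


@dataclass
class WellFit:
    """Point estimate from multi-start optimisation for one well."""

    params: KineticParameters
    phi: np.ndarray
    sigma: float
    log_posterior: float
    start_log_posteriors: list
    n_starts: int


def _gate_current_basis(phi_kinetics, protocol, cond, dt, EK):
    """Simulated current with unit conductance for given kinetics."""
    phi = np.concatenate([[0.0], phi_kinetics])  # ln g = 0
    return _simulate_phi(phi, protocol, cond, dt)


def fit_well(trace: CurrentTrace, protocol, cond: IonicConditions,
             n_starts: int = 10, seed=None,
             bounds: ParameterBounds | None = None,
             x0: np.ndarray | None = None) -> WellFit:
    """Multi-start MAP estimation of the nine parameters for one well.

    Each start draws the eight kinetic parameters log-uniformly from a
    plausible sub-box of the prior, profiles the conductance by linear
    least squares, and refines with bounded trust-region nonlinear least
    squares on the log-kinetics.  The noise SD is profiled analytically
    as sigma_hat = RMS residual.  ``x0`` (a 9-vector phi) adds a
    user-supplied start to the pool.
    """
    bounds = bounds or ParameterBounds()
    rng = np.random.default_rng(seed)
    y = trace.currents
    dt = trace.dt
    EK = reversal_potential(cond)
    n = len(y)
    philo, phihi = bounds.phi_lower, bounds.phi_upper
    glo, ghi = bounds.lower[0], bounds.upper[0]

    def profile_g(base):
        denom = float(base @ base)
        if denom <= 0 or not np.isfinite(denom):
            return None
        g = float(base @ y) / denom
        return min(max(g, glo), ghi)

    def residual(phi_kin):
        try:
            base = _gate_current_basis(phi_kin, protocol, cond, dt, EK)
        except Exception:
            return np.full(n, 1e6)
        if not np.all(np.isfinite(base)):
            return np.full(n, 1e6)
        g = profile_g(base)
        if g is None:
            return np.full(n, 1e6)
        return g * base - y

    starts = []
    if x0 is not None:
        starts.append(np.asarray(x0, dtype=float)[1:])
    lo = np.log(_START_LOWER[1:])
    hi = np.log(_START_UPPER[1:])
    tries = 0
    while len(starts) < n_starts + (x0 is not None) and tries < 50 * n_starts:
        tries += 1
        cand = rng.uniform(lo, hi)
        r = residual(cand)
        if np.all(r < 1e6) and np.ptp(r + y) > 1e-12:  # non-degenerate current
            starts.append(cand)
    if not starts:
        raise FitFailureError("could not generate any viable starting point")

    best = None
    start_logposts = []
    for s in starts:
        try:
            res = optimize.least_squares(
                residual, np.clip(s, philo[1:], phihi[1:]),
                bounds=(philo[1:], phihi[1:]), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception as exc:
            logger.debug("start failed: %s", exc)
            start_logposts.append(-np.inf)
            continue
        ssr = float(2.0 * res.cost)
        sigma = math.sqrt(max(ssr / n, 1e-300))
        lp = -0.5 * n * math.log(2.0 * math.pi * sigma ** 2) \
            - ssr / (2.0 * sigma ** 2)
        start_logposts.append(lp)
        if best is None or ssr < best[0]:
            base = _gate_current_basis(res.x, protocol, cond, dt, EK)
            g = profile_g(base)
            phi_full = np.concatenate([[math.log(g)], res.x])
            best = (ssr, phi_full, sigma, lp)
    if best is None:
        raise FitFailureError("all optimisation starts failed")
    ssr, phi_full, sigma, lp = best
    params = KineticParameters.from_log_vector(
        phi_full, temperature_C=trace.metadata.get("temperature_C"))
    return WellFit(params=params, phi=phi_full, sigma=sigma,
                   log_posterior=lp, start_log_posteriors=start_logposts,
                   n_starts=len(starts))


def _laplace_covariance(phi, sigma, trace, protocol, cond):
    """Gauss-Newton posterior covariance of (phi, ln sigma) at the MAP.

    Used to seed the Metropolis proposal: cov(phi) ~ sigma^2 (J^T J)^-1
    with J the residual Jacobian in phi, and var(ln sigma) ~ 1/(2N).
    """
    dt = trace.dt
    n = len(trace.currents)
    z0 = _simulate_phi(phi, protocol, cond, dt)
    J = np.empty((n, 9))
    h = 1e-5
    for j in range(9):
        up = phi.copy()
        up[j] += h
        J[:, j] = (_simulate_phi(up, protocol, cond, dt) - z0) / h
    jtj = J.T @ J
    try:
        cov = sigma ** 2 * np.linalg.inv(
            jtj + 1e-12 * np.trace(jtj) / 9 * np.eye(9))
    except np.linalg.LinAlgError:
        cov = np.diag(np.full(9, 1e-4))
    full = np.zeros((10, 10))
    full[:9, :9] = 0.5 * (cov + cov.T)
    full[9, 9] = 1.0 / (2.0 * n)
    # guard against a degenerate direction
    full[np.diag_indices(10)] = np.maximum(np.diag(full), 1e-12)
    return full


@dataclass
class WellPosterior:
    """Posterior samples of (phi, ln sigma) for one well."""

    phi_samples: np.ndarray          # (n_kept, 9), all chains pooled
    log_sigma_samples: np.ndarray    # (n_kept,)
    chains: np.ndarray               # (n_chains, n_per_chain, 10)
    acceptance: np.ndarray           # per chain
    point_estimate: WellFit | None
    seed: int | None

    @property
    def phi_mean(self) -> np.ndarray:
        return self.phi_samples.mean(axis=0)

    @property
    def phi_sd(self) -> np.ndarray:
        return self.phi_samples.std(axis=0, ddof=1)


def sample_well(trace: CurrentTrace, protocol, cond: IonicConditions,
                n_iter: int = 20000, n_chains: int = 3, seed=None,
                init: WellFit | np.ndarray | None = None,
                thin: int = 10, bounds: ParameterBounds | None = None,
                adapt_start: int = 200, n_starts: int = 10) -> WellPosterior:
    """Adaptive Metropolis MCMC on (phi, ln sigma) for one well.

    Chains start from the point estimate (jittered per chain), adapt their
    proposal covariance Haario-style with a global scale steered toward a
    0.234 acceptance rate, discard the first half as burn-in, and thin.
    """
    bounds = bounds or ParameterBounds()
    if init is None:
        init = fit_well(trace, protocol, cond, n_starts=n_starts, seed=seed,
                        bounds=bounds)
    point = init if isinstance(init, WellFit) else None
    phi0 = init.phi if isinstance(init, WellFit) else np.asarray(init, float)
    sigma0 = init.sigma if isinstance(init, WellFit) else float(
        np.std(trace.currents - np.mean(trace.currents)) or 1.0)
    y = trace.currents
    n = len(y)
    dt = trace.dt
    sd_y = float(np.std(y)) or 1.0
    ls_lo, ls_hi = math.log(1e-6 * sd_y), math.log(1e3 * sd_y)

    def logpost(x):
        phi, ls = x[:9], x[9]
        if not bounds.contains_phi(phi) or not (ls_lo <= ls <= ls_hi):
            return -np.inf
        try:
            z = _simulate_phi(phi, protocol, cond, dt)
        except Exception:
            return -np.inf
        if not np.all(np.isfinite(z)):
            return -np.inf
        sig2 = math.exp(2.0 * ls)
        return -0.5 * n * math.log(2.0 * math.pi * sig2) \
            - float(np.sum((z - y) ** 2)) / (2.0 * sig2)

    d = 10
    rng = np.random.default_rng(seed)
    try:
        cov0 = _laplace_covariance(phi0, max(sigma0, 1e-12 * sd_y),
                                   trace, protocol, cond)
    except Exception:
        cov0 = np.diag(np.full(d, 1e-4))
    cov0 = cov0 * (2.38 ** 2 / d)
    burn = n_iter // 2
    kept_idx = np.arange(burn, n_iter, thin)
    chains = np.empty((n_chains, len(kept_idx), d))
    acceptance = np.empty(n_chains)
    for c in range(n_chains):
        x = np.concatenate([phi0,
                            [min(max(math.log(max(sigma0, 1e-300)),
                                     ls_lo), ls_hi)]])
        if c > 0:  # jittered starts for convergence diagnostics
            x = x + rng.normal(0.0, 0.005, size=d)
        x[:9] = np.clip(x[:9], bounds.phi_lower, bounds.phi_upper)
        lp = logpost(x)
        if not np.isfinite(lp):
            raise DivergentChainError("initial point has zero posterior")
        mean = x.copy()
        cov = cov0.copy()
        log_scale = 0.0
        n_acc = 0
        keep_ptr = 0
        chol = np.linalg.cholesky(cov)
        for it in range(n_iter):
            prop = x + math.exp(log_scale) * (chol @ rng.standard_normal(d))
            lp_prop = logpost(prop)
            accepted = math.log(rng.uniform()) < lp_prop - lp
            if accepted:
                x, lp = prop, lp_prop
                n_acc += 1
            if it >= adapt_start:
                # offset keeps early gamma small so the seeded proposal
                # covariance is refined, not overwritten, by adaptation
                gamma = (it - adapt_start + 100) ** -0.6
                dx = x - mean
                mean = mean + gamma * dx
                cov = cov + gamma * (np.outer(dx, dx) - cov)
                log_scale += gamma * ((1.0 if accepted else 0.0) - 0.234)
                try:
                    chol = np.linalg.cholesky(
                        cov + 1e-12 * np.eye(d))
                except np.linalg.LinAlgError:
                    pass
            if keep_ptr < len(kept_idx) and it == kept_idx[keep_ptr]:
                chains[c, keep_ptr] = x
                keep_ptr += 1
        acceptance[c] = n_acc / n_iter
        if acceptance[c] < 0.01:
            raise DivergentChainError(
                f"chain {c} acceptance rate {acceptance[c]:.3%} < 1%")
    pooled = chains.reshape(-1, d)
    return WellPosterior(
        phi_samples=pooled[:, :9], log_sigma_samples=pooled[:, 9],
        chains=chains, acceptance=acceptance, point_estimate=point,
        seed=None if seed is None else int(seed))


@dataclass
class HierarchicalPosterior:
    """Samples of the population mean vector mu and covariance Sigma."""

    mu_samples: np.ndarray      # (n_iter, 9)
    sigma_samples: np.ndarray   # (n_iter, 9, 9)
    n_wells: int
    n_rejected: int
    seed: int | None

    @property
    def mu_mean(self) -> np.ndarray:
        return self.mu_samples.mean(axis=0)

    def mu_credible_interval(self, level: float = 0.95) -> np.ndarray:
        """Central credible interval per coordinate; shape (9, 2)."""
        alpha = 100.0 * (1.0 - level) / 2.0
        lo = np.percentile(self.mu_samples, alpha, axis=0)
        hi = np.percentile(self.mu_samples, 100.0 - alpha, axis=0)
        return np.stack([lo, hi], axis=1)


def fit_hierarchical(well_samples, n_iter: int = 5000, seed=None,
                     mu0: np.ndarray | None = None, kappa0: float = 1e-4,
                     nu0: float = 11.0,
                     psi0: np.ndarray | None = None) -> HierarchicalPosterior:
    """Pseudo-Metropolis-within-Gibbs for the population (mu, Sigma).

    ``well_samples`` is a list (one entry per well) of either
    :class:`WellPosterior` objects or (n_i, 9) arrays of phi samples.
    Each iteration draws one phi_j uniformly from every well's pool (the
    "pseudo" step) and then performs the conjugate Gibbs update of
    (mu, Sigma) under a weakly informative normal-inverse-Wishart
    hyperprior (nu0 = 9 + 2; psi0 a small diagonal scale; mu0 defaults to
    the midpoint of the default prior box).
    """
    pools = [w.phi_samples if isinstance(w, WellPosterior)
             else np.asarray(w, dtype=float) for w in well_samples]
    if len(pools) < 2:
        raise ValueError("hierarchical fit needs >= 2 wells")
    for p in pools:
        if p.ndim != 2 or p.shape[1] != 9 or len(p) < 1:
            raise ValueError("each well pool must be an (n, 9) array")
    d = 9
    ne = len(pools)
    b = ParameterBounds()
    if mu0 is None:
        mu0 = 0.5 * (b.phi_lower + b.phi_upper)
    mu0 = np.asarray(mu0, dtype=float)
    if psi0 is None:
        psi0 = 0.01 * np.eye(d)
    rng = np.random.default_rng(seed)

    mu_samples = np.empty((n_iter, d))
    sigma_samples = np.empty((n_iter, d, d))
    n_rejected = 0
    nun = nu0 + ne
    kappan = kappa0 + ne
    for it in range(n_iter):
        phis = np.stack([p[rng.integers(len(p))] for p in pools])
        phibar = phis.mean(axis=0)
        diff = phis - phibar
        S = diff.T @ diff
        dm = phibar - mu0
        psin = psi0 + S + (kappa0 * ne / kappan) * np.outer(dm, dm)
        psin = 0.5 * (psin + psin.T)
        for _ in range(10):
            sigma = stats.invwishart.rvs(df=nun, scale=psin,
                                         random_state=rng)
            try:
                np.linalg.cholesky(sigma)
                break
            except np.linalg.LinAlgError:
                n_rejected += 1
        mun = (kappa0 * mu0 + ne * phibar) / kappan
        mu = rng.multivariate_normal(mun, sigma / kappan, method="eigh")
        mu_samples[it] = mu
        sigma_samples[it] = sigma
    return HierarchicalPosterior(
        mu_samples=mu_samples, sigma_samples=sigma_samples, n_wells=ne,
        n_rejected=n_rejected,
        seed=None if seed is None else int(seed))
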