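"""Likelihood correctness, point estimation, MCMC, hierarchical pooling."""

import math

import numpy as np
import pytest
from scipy import stats

import hergtemp as ht
from hergtemp.inference import ParameterBounds


@pytest.fixture(scope="module")
def clean_trace(truth25, mini_protocol, cond25):
    return ht.simulate_step_analytic(truth25, mini_protocol, cond25, dt=1.0)


class TestLogLikelihood:
    def test_zero_residual_value(self, truth25, mini_protocol, cond25,
                                 clean_trace):
        sigma = 0.3
        n = len(clean_trace.currents)
        ll = ht.log_likelihood(truth25.log_vector(), sigma, clean_trace,
                               mini_protocol, cond25)
        assert ll == pytest.approx(
            -0.5 * n * math.log(2 * math.pi * sigma ** 2), rel=1e-12)

    def test_any_perturbation_decreases_likelihood(self, truth25,
                                                   mini_protocol, cond25,
                                                   clean_trace):
        phi = truth25.log_vector()
        base = ht.log_likelihood(phi, 0.3, clean_trace, mini_protocol,
                                 cond25)
        rng = np.random.default_rng(1)
        for _ in range(5):
            shifted = phi + rng.normal(0, 0.02, 9)
            assert ht.log_likelihood(shifted, 0.3, clean_trace,
                                     mini_protocol, cond25) < base

    def test_matches_independent_gaussian_density(self, truth25,
                                                  mini_protocol, cond25):
        # tiny trace; oracle is scipy's normal log-density summed
        rng = np.random.default_rng(2)
        short = ht.StepProtocol.from_steps([(5.0, -40.0)])
        clean = ht.simulate_step_analytic(truth25, short, cond25, dt=1.0)
        y = clean.currents + rng.normal(0, 0.1, len(clean.currents))
        trace = ht.CurrentTrace(clean.times, y)
        sigma = 0.17
        ll = ht.log_likelihood(truth25.log_vector(), sigma, trace, short,
                               cond25)
        oracle = stats.norm.logpdf(y, loc=clean.currents,
                                   scale=sigma).sum()
        assert ll == pytest.approx(oracle, rel=1e-10)

    def test_sigma_must_be_positive(self, truth25, mini_protocol, cond25,
                                    clean_trace):
        with pytest.raises(ValueError):
            ht.log_likelihood(truth25.log_vector(), 0.0, clean_trace,
                              mini_protocol, cond25)


class TestLogPosterior:
    def test_outside_bounds_is_minus_inf(self, truth25, mini_protocol,
                                         cond25, clean_trace):
        phi = truth25.log_vector().copy()
        phi[2] = math.log(0.5)  # sensitivity above the 0.4 / mV bound
        assert ht.log_posterior(phi, 0.3, clean_trace, mini_protocol,
                                cond25) == -np.inf

    def test_inside_equals_likelihood(self, truth25, mini_protocol, cond25,
                                      clean_trace):
        phi = truth25.log_vector()
        lp = ht.log_posterior(phi, 0.3, clean_trace, mini_protocol, cond25)
        ll = ht.log_likelihood(phi, 0.3, clean_trace, mini_protocol, cond25)
        assert lp == ll

    def test_boundary_included(self, truth25, mini_protocol, cond25,
                               clean_trace):
        bounds = ParameterBounds()
        phi = truth25.log_vector().copy()
        phi[2] = bounds.phi_upper[2]  # exactly on the closed bound
        assert np.isfinite(ht.log_posterior(phi, 0.3, clean_trace,
                                            mini_protocol, cond25))

    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            ParameterBounds(lower=np.full(9, 2.0), upper=np.ones(9))


class TestFitWell:
    def test_noiseless_recovery(self, truth25, mini_protocol, cond25,
                                clean_trace):
        fit = ht.fit_well(clean_trace, mini_protocol, cond25, n_starts=6,
                          seed=5)
        assert np.max(np.abs(fit.phi - truth25.log_vector())) < 1e-6

    def test_noisy_recovery_in_prediction_space(self, noisy_mini_well,
                                                mini_protocol, cond25,
                                                mini_well_fit):
        # the short protocol leaves some coordinates weakly identified, so
        # recovery is judged where it is meaningful: the fitted model's
        # prediction sits within the noise floor of the clean truth
        clean = ht.simulate_step_analytic(noisy_mini_well.params,
                                          mini_protocol, cond25, dt=1.0)
        pred = ht.simulate_step_analytic(mini_well_fit.params,
                                         mini_protocol, cond25, dt=1.0)
        resid = np.sqrt(np.mean((pred.currents - clean.currents) ** 2))
        assert resid < 0.2 * noisy_mini_well.noise_sd
        assert mini_well_fit.sigma == pytest.approx(
            noisy_mini_well.noise_sd, rel=0.1)

    def test_idempotent_at_optimum(self, noisy_mini_well, mini_protocol,
                                   cond25, mini_well_fit):
        refit = ht.fit_well(noisy_mini_well.trace, mini_protocol, cond25,
                            n_starts=0, seed=1, x0=mini_well_fit.phi)
        assert refit.log_posterior - mini_well_fit.log_posterior < 1e-6 \
            + 1e-9 * abs(mini_well_fit.log_posterior)

    def test_reports_all_start_log_posteriors(self, mini_well_fit):
        assert len(mini_well_fit.start_log_posteriors) == 6
        assert max(mini_well_fit.start_log_posteriors) == pytest.approx(
            mini_well_fit.log_posterior)


class TestSampleWell:
    def test_fixed_seed_identical_chain(self, noisy_mini_well,
                                        mini_protocol, cond25,
                                        mini_well_fit):
        kw = dict(n_iter=400, n_chains=1, thin=2, seed=99,
                  init=mini_well_fit)
        a = ht.sample_well(noisy_mini_well.trace, mini_protocol, cond25,
                           **kw)
        b = ht.sample_well(noisy_mini_well.trace, mini_protocol, cond25,
                           **kw)
        assert np.array_equal(a.phi_samples, b.phi_samples)

    def test_samples_respect_bounds_and_acceptance(self, noisy_mini_well,
                                                   mini_protocol, cond25,
                                                   mini_well_fit):
        post = ht.sample_well(noisy_mini_well.trace, mini_protocol, cond25,
                              n_iter=600, n_chains=2, thin=2, seed=42,
                              init=mini_well_fit)
        b = ParameterBounds()
        assert np.all(post.phi_samples >= b.phi_lower)
        assert np.all(post.phi_samples <= b.phi_upper)
        assert np.all(post.acceptance > 0.01)

    def test_posterior_mean_near_truth(self, noisy_mini_well, mini_protocol,
                                       cond25, mini_well_fit):
        post = ht.sample_well(noisy_mini_well.trace, mini_protocol, cond25,
                              n_iter=4000, n_chains=1, thin=5, seed=7,
                              init=mini_well_fit)
        z = (post.phi_mean - noisy_mini_well.params.log_vector()) \
            / post.phi_sd
        assert np.all(np.abs(z) < 4.0)

    def test_convergence_diagnostic_on_staircase(self, temp_truth,
                                                 staircase, cond25):
        import arviz as az
        truth = ht.hierarchical_truth_at(temp_truth, 25.0,
                                         log_sd=np.zeros(9))
        ds = ht.generate_dataset(truth, staircase, 1, seed=3, dt=2.0)
        fit = ht.fit_well(ds.wells[0].trace, staircase, cond25, n_starts=6,
                          seed=5)
        post = ht.sample_well(ds.wells[0].trace, staircase, cond25,
                              n_iter=8000, n_chains=3, thin=10, seed=11,
                              init=fit)
        rhat = az.rhat(az.convert_to_dataset(post.chains[:, :, :9]))
        assert float(np.max(rhat.to_array().values)) < 1.05


class TestFitHierarchical:
    def make_pools(self, mu, sigma_sd, n_wells, pool_sd, rng):
        """Pools that mimic narrow per-well posteriors around phi_j."""
        pools = []
        for _ in range(n_wells):
            phi_j = mu + rng.normal(0, sigma_sd, 9)
            pools.append(phi_j + rng.normal(0, pool_sd, (50, 9)))
        return pools

    def test_degenerate_variability_recovers_common_mean(self, truth25):
        rng = np.random.default_rng(0)
        mu = truth25.log_vector()
        pools = self.make_pools(mu, 0.0, 10, 0.01, rng)
        hier = ht.fit_hierarchical(pools, n_iter=2000, seed=1)
        assert np.max(np.abs(hier.mu_mean - mu)) < 0.02

    def test_well_order_is_exchangeable(self, truth25):
        rng = np.random.default_rng(3)
        mu = truth25.log_vector()
        pools = self.make_pools(mu, 0.08, 12, 0.01, rng)
        h1 = ht.fit_hierarchical(pools, n_iter=2000, seed=5)
        h2 = ht.fit_hierarchical(pools[::-1], n_iter=2000, seed=5)
        # statistically unchanged: means agree within Monte-Carlo error
        mc = 4 * np.abs(h1.mu_samples.std(axis=0)) / math.sqrt(2000.0)
        assert np.all(np.abs(h1.mu_mean - h2.mu_mean)
                      < np.maximum(mc, 0.02))

    def test_sigma_samples_positive_definite(self, truth25):
        rng = np.random.default_rng(4)
        pools = self.make_pools(truth25.log_vector(), 0.1, 5, 0.02, rng)
        hier = ht.fit_hierarchical(pools, n_iter=500, seed=2)
        for s in hier.sigma_samples[::50]:
            np.linalg.cholesky(s)  # raises if not PD

    def test_posterior_mean_mu_is_unbiased(self, truth25):
        # across replicates, the per-coordinate bias of the posterior-mean
        # population mean stays within Monte-Carlo error of zero
        mu = truth25.log_vector()
        sigma_sd = 0.1
        n_rep, n_wells = 10, 20
        rng = np.random.default_rng(11)
        means = []
        for _ in range(n_rep):
            pools = self.make_pools(mu, sigma_sd, n_wells, 0.02, rng)
            hier = ht.fit_hierarchical(pools, n_iter=800, seed=rng.integers(
                2 ** 31))
            means.append(hier.mu_mean)
        bias = np.mean(means, axis=0) - mu
        se = sigma_sd / math.sqrt(n_rep * n_wells)
        assert np.all(np.abs(bias) < 4 * se)

    def test_requires_two_wells(self, truth25):
        with pytest.raises(ValueError):
            ht.fit_hierarchical([truth25.log_vector()[None, :]], seed=0)

    def test_rejects_malformed_pool(self):
        with pytest.raises(ValueError):
            ht.fit_hierarchical([np.zeros((5, 3)), np.zeros((5, 3))], seed=0)
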