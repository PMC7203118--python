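"""Threshold-exponential NEC model: mean function, posterior, sampler."""

from math import lgamma, log, pi

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phycotox.nec import PARAM_NAMES, NECModel, NECResults


def _sim_data(seed=0, alpha=1.0, beta=2.0, gamma=np.log(10), delta=0.0,
              sigma=0.05, n_conc=8, reps=5):
    rng = np.random.default_rng(seed)
    x = np.repeat(np.log(np.geomspace(1, 100, n_conc)), reps)
    mu = alpha * np.exp(-beta * np.maximum(x - gamma, 0.0)) - delta
    return x, mu + rng.normal(0, sigma, x.size)


class TestModelMean:
    @pytest.mark.parametrize("x_off", [-3.0, -0.5, 0.0])
    def test_flat_at_and_below_threshold(self, x_off):
        params = (0.9, 5.0, 1.0, 0.1, 0.05)
        assert NECModel.model_mean(params, 1.0 + x_off) == pytest.approx(0.8)

    def test_zero_decay_rate_flat_everywhere(self):
        assert NECModel.model_mean((1.0, 0.0, 0.0, 0.2), 7.3) == pytest.approx(0.8)

    def test_halving_distance_closed_form(self):
        # alpha=1, delta=0, beta=1: at gamma + ln 2 the mean halves
        g = 2.0
        assert NECModel.model_mean((1.0, 1.0, g, 0.0), g + np.log(2)) == \
            pytest.approx(0.5, rel=1e-12)

    def test_continuous_at_threshold_and_nonincreasing(self):
        params = (1.2, 3.0, 0.7, 0.1)
        eps = 1e-9
        below = NECModel.model_mean(params, 0.7 - eps)
        above = NECModel.model_mean(params, 0.7 + eps)
        assert above == pytest.approx(below, abs=1e-7)
        grid = np.linspace(-3, 5, 400)
        vals = NECModel.model_mean(params, grid)
        assert np.all(np.diff(vals) <= 1e-12)


class TestLogPosterior:
    def _hand_log_posterior(self, params, x, y):
        a, b, g, d, s = params
        ll = 0.0
        for xi, yi in zip(x, y):
            mu = a * np.exp(-b * max(xi - g, 0.0)) - d
            ll += -0.5 * log(2 * pi * s ** 2) - (yi - mu) ** 2 / (2 * s ** 2)
        lp = (0.5 * log(0.1 / (2 * pi)) - 0.5 * 0.1 * a ** 2
              + 1e-4 * log(1e-4) - lgamma(1e-4) + (1e-4 - 1) * log(b) - 1e-4 * b
              + 0.5 * log(0.01 / (2 * pi)) - 0.5 * 0.01 * g ** 2
              + 0.5 * log(0.1 / (2 * pi)) - 0.5 * 0.1 * d ** 2
              - log(29.0))
        return ll + lp

    def test_term_by_term_hand_sum_on_five_points(self):
        x = np.array([0.0, 0.5, 1.0, 1.5, 2.0])
        y = np.array([1.02, 0.98, 0.8, 0.5, 0.3])
        model = NECModel(x, y)
        params = (1.0, 1.5, 0.8, 0.02, 0.07)
        assert model.log_posterior(params) == pytest.approx(
            self._hand_log_posterior(params, x, y), abs=1e-10)

    @pytest.mark.parametrize("params", [
        (1.0, 1.0, 0.0, 0.0, 0.0),     # sigma at 0
        (1.0, 1.0, 0.0, 0.0, 29.01),   # sigma above the uniform upper bound
        (1.0, -0.1, 0.0, 0.0, 0.1),    # negative decay rate
        (1.0, 0.0, 0.0, 0.0, 0.1),     # zero decay rate outside gamma support
    ])
    def test_out_of_support_is_minus_inf(self, params):
        x, y = _sim_data(seed=1)
        assert NECModel(x, y).log_posterior(params) == -np.inf

    def test_beta_prior_term_matches_scipy_gamma(self):
        x, y = _sim_data(seed=2)
        m = NECModel(x, y)
        base = (1.0, 1.0, 0.5, 0.0, 0.1)
        other = (1.0, 2.5, 0.5, 0.0, 0.1)
        diff = m.log_prior(other) - m.log_prior(base)
        expected = (stats.gamma.logpdf(2.5, a=1e-4, scale=1e4)
                    - stats.gamma.logpdf(1.0, a=1e-4, scale=1e4))
        assert diff == pytest.approx(expected, abs=1e-10)

    def test_equal_residuals_rank_identically(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y1 = NECModel.model_mean((1.0, 1.0, 1.0, 0.0), x) + 0.05
        m1 = NECModel(x, np.asarray(y1))
        # same residual vector under a different mean surface
        y2 = NECModel.model_mean((0.8, 2.0, 1.5, -0.1), x) + 0.05
        m2 = NECModel(x, np.asarray(y2))
        ll1 = m1.log_likelihood((1.0, 1.0, 1.0, 0.0, 0.1))
        ll2 = m2.log_likelihood((0.8, 2.0, 1.5, -0.1, 0.1))
        assert ll1 == pytest.approx(ll2, abs=1e-12)

    def test_scaling_equivariance_of_likelihood(self):
        """With delta=0, scaling y -> k*y is absorbed by alpha -> k*alpha,
        sigma -> k*sigma up to the Jacobian n*log k, for a grid of small k."""
        x, y = _sim_data(seed=3)
        n = y.size
        base = (1.0, 2.0, np.log(10), 0.0, 0.05)
        ll = NECModel(x, y).log_likelihood(base)
        for k in (0.5, 1.5, 2.0, 3.0):
            scaled = (k * base[0], base[1], base[2], 0.0, k * base[4])
            ll_k = NECModel(x, k * y).log_likelihood(scaled)
            assert ll_k == pytest.approx(ll - n * log(k), rel=1e-12)


class TestSampler:
    def test_same_seed_identical_chains(self):
        x, y = _sim_data(seed=4)
        m = NECModel(x, y)
        a = m.fit(chains=2, burn_in=200, draws=200, seed=9)
        b = m.fit(chains=2, burn_in=200, draws=200, seed=9)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_posterior_invariant_to_data_order(self):
        x, y = _sim_data(seed=5)
        m1 = NECModel(x, y)
        perm = np.random.default_rng(0).permutation(x.size)
        m2 = NECModel(x[perm], y[perm])
        a = m1.fit(chains=1, burn_in=300, draws=300, seed=2)
        b = m2.fit(chains=1, burn_in=300, draws=300, seed=2)
        np.testing.assert_allclose(a.draws, b.draws, rtol=0, atol=1e-12)

    def test_parameter_recovery_single_dataset(self):
        x, y = _sim_data(seed=6)
        res = NECModel(x, y).fit(chains=3, burn_in=2000, draws=1500, seed=1)
        g = res.draws[:, :, 2].ravel()
        lo, med, hi = np.quantile(g, [0.025, 0.5, 0.975])
        assert lo <= np.log(10) <= hi
        assert abs(med - np.log(10)) < 0.2
        nec = res.nec_summary()
        assert nec["ci_low"] <= nec["nec"] <= nec["ci_high"]

    def test_flat_data_gives_diffuse_threshold(self):
        """With no decline the threshold cannot be identified: its posterior
        SD stays a sizable fraction of the tested log-range."""
        rng = np.random.default_rng(12)
        x = np.repeat(np.log(np.geomspace(1, 100, 6)), 5)
        y = 1.0 + rng.normal(0, 0.03, x.size)
        res = NECModel(x, y).fit(chains=2, burn_in=1500, draws=1000, seed=3)
        g = res.draws[:, :, 2].ravel()
        assert g.std() > 0.3

    def test_acceptance_rate_in_target_band(self):
        x, y = _sim_data(seed=7)
        res = NECModel(x, y).fit(chains=2, burn_in=2000, draws=1000, seed=5)
        assert np.all(res.acceptance > 0.1) and np.all(res.acceptance < 0.55)


class TestPriorSampling:
    def test_direct_prior_moments(self):
        m = NECModel(*_sim_data(seed=8))
        draws = m.sample_prior(200_000, seed=0)
        assert draws["alpha"].std() == pytest.approx(np.sqrt(10.0), rel=0.02)
        assert draws["gamma"].std() == pytest.approx(10.0, rel=0.02)
        assert draws["delta"].std() == pytest.approx(np.sqrt(10.0), rel=0.02)
        assert draws["sigma"].mean() == pytest.approx(14.5, rel=0.02)
        assert draws["sigma"].std() == pytest.approx(29 / np.sqrt(12), rel=0.02)

    def test_likelihood_disabled_mcmc_reproduces_normal_prior_sd(self):
        """Prior-only MCMC checks the log-posterior's prior terms carry the
        precision (not SD) parameterization."""
        m = NECModel(*_sim_data(seed=9))
        res = m.fit(chains=4, burn_in=2000, draws=4000, seed=11,
                    use_likelihood=False)
        post = res.posterior
        assert post["alpha"].std() == pytest.approx(np.sqrt(10.0), rel=0.10)
        assert post["gamma"].std() == pytest.approx(10.0, rel=0.10)
        assert post["delta"].std() == pytest.approx(np.sqrt(10.0), rel=0.10)
        assert post["sigma"].mean() == pytest.approx(14.5, rel=0.10)


class TestSummaries:
    def _degenerate_results(self, g0=1.3):
        m = NECModel(*_sim_data(seed=10))
        draws = np.tile(np.array([1.0, 2.0, g0, 0.0, 0.05]), (2, 50, 1))
        return NECResults(m, draws, np.full((2, 5), 0.3),
                          {"chains": 2, "burn_in": 0, "draws": 50,
                           "seed": 0, "use_likelihood": True, "log_base": "e"})

    def test_degenerate_posterior_point_equals_bounds(self):
        nec = self._degenerate_results(1.3).nec_summary()
        assert nec["nec"] == nec["ci_low"] == nec["ci_high"] == \
            pytest.approx(np.exp(1.3))

    def test_ci_bounds_are_exp_of_gamma_quantiles(self):
        x, y = _sim_data(seed=11)
        res = NECModel(x, y).fit(chains=2, burn_in=800, draws=500, seed=13)
        g = res.draws[:, :, 2].ravel()
        nec = res.nec_summary()
        assert nec["ci_low"] == pytest.approx(np.exp(np.quantile(g, 0.025)))
        assert nec["ci_high"] == pytest.approx(np.exp(np.quantile(g, 0.975)))

    def test_posterior_ecx_between_nec_and_max(self):
        x, y = _sim_data(seed=12)
        res = NECModel(x, y).fit(chains=2, burn_in=1500, draws=1000, seed=17)
        ec50 = res.ecx(50)
        nec = res.nec_summary()
        assert nec["nec"] < ec50["ecx"]
        assert ec50["ci_low"] <= ec50["ecx"] <= ec50["ci_high"]

    def test_summary_text_mentions_convergence(self):
        res = self._degenerate_results()
        assert "R-hat" in res.summary()
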