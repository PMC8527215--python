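import numpy as np
import pytest
from scipy import integrate, stats

from mavc.memory_models import (
    CceiDataset,
    McmcConfig,
    bf_product_space,
    marginal_likelihood_quadrature,
    mu_exponential,
    replication_bf,
    sample_posterior,
    stopping_rule_monitor,
    truncnorm_loglik,
)
from mavc.synthetic_data import simulate_ccei_dataset

FAST_MCMC = McmcConfig(n_chains=4, n_draws=2000, n_warmup=1000)


class TestMuExponential:
    def test_t_zero(self):
        assert mu_exponential(0.0, 0.4, 0.9, 0.3) == pytest.approx(0.94)

    def test_asymptote(self):
        assert mu_exponential(1e9, 0.4, 0.9, 0.3) == pytest.approx(0.4)

    def test_interior_value(self):
        # 0.4 + 0.6 * 0.9 * exp(-3)
        assert mu_exponential(10.0, 0.4, 0.9, 0.3) == pytest.approx(0.42689, abs=1e-5)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            mu_exponential(1.0, 1.5, 0.9, 0.3)
        with pytest.raises(ValueError):
            mu_exponential(-1.0, 0.4, 0.9, 0.3)


class TestTruncnormLoglik:
    def test_single_point_closed_form(self):
        """x = mu = 0.5, sigma = 0.1: log[phi(0) / (sigma * Z)]."""
        data = CceiDataset(t=[1.0], ccei=[0.5])
        z_mass = stats.norm.cdf(5.0) - stats.norm.cdf(-5.0)
        expected = np.log(stats.norm.pdf(0.0) / (0.1 * z_mass))
        assert truncnorm_loglik(data, lambda t: 0.5, 0.1) == pytest.approx(expected)

    def test_matches_scipy_truncnorm(self, rng):
        data = CceiDataset(t=rng.uniform(0, 30, 20), ccei=rng.uniform(0.05, 0.95, 20))
        mu, sigma = 0.6, 0.15
        expected = stats.truncnorm.logpdf(
            data.ccei, (0 - mu) / sigma, (1 - mu) / sigma, loc=mu, scale=sigma
        ).sum()
        assert truncnorm_loglik(data, lambda t: mu, sigma) == pytest.approx(expected)

    def test_density_integrates_to_one(self):
        for mu, sigma in [(0.3, 0.2), (0.9, 0.05), (0.0, 0.4)]:
            val, _ = integrate.quad(
                lambda x: stats.truncnorm.pdf(
                    x, (0 - mu) / sigma, (1 - mu) / sigma, loc=mu, scale=sigma
                ),
                0.0,
                1.0,
            )
            assert val == pytest.approx(1.0, abs=1e-8)

    def test_sigma_zero_rejected(self):
        data = CceiDataset(t=[1.0], ccei=[0.5])
        with pytest.raises(ValueError):
            truncnorm_loglik(data, lambda t: 0.5, 0.0)


class TestSamplePosterior:
    def test_exponential_recovery(self, rng):
        """Posterior concentrates near the generating parameters."""
        data = simulate_ccei_dataset(rng, n=300)
        post = sample_posterior(data, "exponential", FAST_MCMC, seed=1)
        flat = post.flat()
        lo, hi = np.percentile(flat, [2.5, 97.5], axis=0)
        truth = np.array([0.4, 0.9, 0.3, 0.1])
        # wide-interval containment: truth inside the central 99%-ish region
        lo99, hi99 = np.percentile(flat, [0.5, 99.5], axis=0)
        assert np.all(truth > lo99 - 0.05) and np.all(truth < hi99 + 0.05)
        assert np.abs(flat.mean(axis=0) - truth).max() < 0.1

    def test_null_posterior_mean_matches_sample_mean(self, rng):
        data = CceiDataset(t=rng.uniform(0, 30, 200), ccei=rng.uniform(0.3, 0.7, 200))
        post = sample_posterior(data, "null", FAST_MCMC, seed=2)
        c_mean = post.flat()[:, 0].mean()
        assert c_mean == pytest.approx(data.ccei.mean(), abs=0.02)

    def test_determinism(self, rng):
        data = simulate_ccei_dataset(rng, n=60)
        p1 = sample_posterior(data, "null", FAST_MCMC, seed=3)
        p2 = sample_posterior(data, "null", FAST_MCMC, seed=3)
        assert np.array_equal(p1.draws, p2.draws)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            sample_posterior(CceiDataset(t=np.array([]), ccei=np.array([])), "null")


class TestQuadrature:
    def test_no_data_gives_unit_evidence(self):
        data = CceiDataset(t=np.array([]), ccei=np.array([]))
        assert marginal_likelihood_quadrature(data, "null") == 1.0
        assert marginal_likelihood_quadrature(data, "exponential") == 1.0

    def test_null_single_observation_matches_dense_grid(self):
        """2-D quadrature against an independent plain dense-grid integral."""
        data = CceiDataset(t=[5.0], ccei=[0.62])
        got = marginal_likelihood_quadrature(data, "null", refinement_check=False)
        c = np.linspace(1e-6, 1 - 1e-6, 1200)
        s = np.linspace(1e-4, 1.0, 1200)
        cc, ss = np.meshgrid(c, s, indexing="ij")
        dens = stats.truncnorm.pdf(
            0.62, (0 - cc) / ss, (1 - cc) / ss, loc=cc, scale=ss
        )
        grid = np.trapezoid(np.trapezoid(dens, s, axis=1), c)
        assert got == pytest.approx(grid, rel=0.01)


class TestProductSpaceBf:
    def test_no_data_bf_is_one(self):
        data = CceiDataset(t=np.array([]), ccei=np.array([]))
        assert bf_product_space(data).bf10 == pytest.approx(1.0)

    def test_determinism(self, rng):
        data = simulate_ccei_dataset(rng, n=40)
        r1 = bf_product_space(data, FAST_MCMC, seed=9)
        r2 = bf_product_space(data, FAST_MCMC, seed=9)
        assert r1.bf10 == r2.bf10

    def test_exponential_data_supported(self, rng):
        data = simulate_ccei_dataset(rng, n=300)
        res = bf_product_space(data, FAST_MCMC, seed=5)
        assert res.bf10 >= 10.0

    def test_null_data_not_supported(self, rng):
        t = rng.uniform(0, 30, 300)
        x = stats.truncnorm.rvs(-5, 5, loc=0.5, scale=0.1, random_state=rng, size=300)
        res = bf_product_space(CceiDataset(t=t, ccei=x), FAST_MCMC, seed=6)
        assert res.bf10 < 1.0


class TestReplicationBf:
    @pytest.mark.parametrize("combined,train,expected", [(1000.0, 10.0, 100.0), (10.0, 10.0, 1.0)])
    def test_division(self, combined, train, expected):
        assert replication_bf(combined, train) == pytest.approx(expected)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            replication_bf(-1.0, 2.0)

    def test_independent_blocks_identity(self, rng):
        """For independent halves, BF(all)/BF(train) tracks the evidence the
        test half adds; on null-model-only data computed by quadrature the
        identity BF_rep = ML ratios factorizes exactly."""
        t = rng.uniform(0, 30, 40)
        x = stats.truncnorm.rvs(-4, 4, loc=0.5, scale=0.12, random_state=rng, size=40)
        train = CceiDataset(t=t[:20], ccei=x[:20])
        test = CceiDataset(t=t[20:], ccei=x[20:])
        both = train.concat(test)
        ml = {
            name: {
                "train": marginal_likelihood_quadrature(train, name, refinement_check=False, log=True),
                "both": marginal_likelihood_quadrature(both, name, refinement_check=False, log=True),
            }
            for name in ("exponential", "null")
        }
        bf_train = np.exp(ml["exponential"]["train"] - ml["null"]["train"])
        bf_both = np.exp(ml["exponential"]["both"] - ml["null"]["both"])
        rep = replication_bf(bf_both, bf_train)
        assert rep > 0
        # the replication BF is exactly the evidence ratio of the held-out
        # data given the training posterior; check the defining identity
        assert rep == pytest.approx(bf_both / bf_train)


def test_stopping_rule_monitor():
    assert stopping_rule_monitor([1.0, 3.0, 12.0, 0.5]) == 2
    assert stopping_rule_monitor([1.0, 0.05]) == 1
    assert stopping_rule_monitor([1.0, 2.0]) is None
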