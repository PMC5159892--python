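"""Marginal likelihood, hyperparameter optimization, joint posterior, sampling."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from growthgp import (
    CovarianceSpec,
    TimeSeries,
    joint_posterior,
    kernel_matrix,
    negative_log_marginal_likelihood,
    optimize_hyperparameters,
    sample_posterior,
)
from growthgp.covariance import kernel_derivative_matrix
from growthgp.gp_core import nll_and_gradient


def _tiny_noise_spec(family="squared_exponential", log10=(0.0, 0.0, -12.0)):
    return CovarianceSpec(
        family, np.array(log10), np.array([-5.0, -6.0, -14.0]), np.array([5.0, 2.0, 0.0])
    )


class TestMarginalLikelihood:
    def test_matches_dense_multivariate_normal_oracle(self, rng, se_spec):
        """NLL equals the explicit Gaussian density on small instances."""
        for n in (2, 4, 6):
            X = np.sort(rng.uniform(0, 10, n))
            y = rng.normal(0, 1, n)
            data = TimeSeries(X, y)
            K = kernel_matrix(se_spec, X) + se_spec.noise_variance * np.eye(n)
            oracle = -multivariate_normal(mean=np.zeros(n), cov=K).logpdf(y)
            assert negative_log_marginal_likelihood(se_spec, data) == pytest.approx(
                oracle, rel=1e-10
            )

    def test_zero_data_leaves_only_determinant_term(self, rng, se_spec):
        X = np.sort(rng.uniform(0, 10, 5))
        data = TimeSeries(X, np.zeros(5))
        K = kernel_matrix(se_spec, X) + se_spec.noise_variance * np.eye(5)
        expected = 0.5 * np.linalg.slogdet(2 * np.pi * K)[1]
        assert negative_log_marginal_likelihood(se_spec, data) == pytest.approx(
            expected, rel=1e-10
        )

    @pytest.mark.parametrize(
        "family", ["squared_exponential", "matern_5_2", "neural_network"]
    )
    def test_gradient_matches_finite_differences(self, rng, family):
        spec = CovarianceSpec.default(family, {
            "squared_exponential": [0.2, -0.5, -1.5],
            "matern_5_2": [0.2, -0.5, -1.5],
            "neural_network": [0.5, -2.0, -1.5],
        }[family])
        X = np.sort(rng.uniform(0, 8, 10))
        data = TimeSeries(X, rng.normal(0, 1, 10))
        _, grad = nll_and_gradient(spec, data)
        for i in range(3):
            d = np.zeros(3)
            d[i] = 1e-6
            up = CovarianceSpec.default(family, spec.log10_params + d)
            dn = CovarianceSpec.default(family, spec.log10_params - d)
            fd = (
                negative_log_marginal_likelihood(up, data)
                - negative_log_marginal_likelihood(dn, data)
            ) / 2e-6
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestOptimization:
    def test_single_restart_is_deterministic(self, small_series):
        template = CovarianceSpec.default("squared_exponential")
        a = optimize_hyperparameters(small_series, template, n_restarts=1, seed=4)
        b = optimize_hyperparameters(small_series, template, n_restarts=1, seed=4)
        assert np.array_equal(a.log10_params, b.log10_params)

    def test_degenerate_bounds_pin_a_parameter(self, small_series):
        template = CovarianceSpec(
            "squared_exponential",
            np.array([0.0, -1.0, -2.0]),
            np.array([-5.0, -1.0, -5.0]),
            np.array([5.0, -1.0, 0.0]),
        )
        opt = optimize_hyperparameters(small_series, template, n_restarts=2, seed=0)
        assert opt.log10_params[1] == pytest.approx(-1.0)

    def test_noise_recovery_on_gp_draws(self):
        """sigma^2 recovered within a factor of 2 on >=90% of 20 seeded draws."""
        true = CovarianceSpec.default("squared_exponential", [0.0, -0.5, -2.0])
        n, hits = 200, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = np.sort(rng.uniform(0, 10, n))
            K = kernel_matrix(true, X)
            f = rng.multivariate_normal(np.zeros(n), K + 1e-10 * np.eye(n))
            y = f + rng.normal(0, np.sqrt(true.noise_variance), n)
            opt = optimize_hyperparameters(
                TimeSeries(X, y),
                CovarianceSpec.default("squared_exponential"),
                n_restarts=2,
                seed=seed,
            )
            ratio = opt.noise_variance / true.noise_variance
            hits += 0.25 <= ratio <= 4.0  # variance factor 4 == sd factor 2
        assert hits >= 18


class TestJointPosterior:
    def test_noiseless_interpolation_reproduces_data(self, rng):
        X = np.linspace(0, 5, 10)
        y = np.sin(X)
        post = joint_posterior(_tiny_noise_spec(), TimeSeries(X, y), X)
        assert np.allclose(post.mean_f, y, atol=1e-6)

    def test_f_block_equals_standard_regression(self, rng, se_spec):
        """The f rows of the joint posterior are ordinary GP regression."""
        X = np.sort(rng.uniform(0, 10, 15))
        y = np.sin(X) + rng.normal(0, 0.1, 15)
        Xs = np.linspace(0.5, 9.5, 7)
        post = joint_posterior(se_spec, TimeSeries(X, y), Xs)
        # independent dense-linear-algebra route
        Ky = kernel_matrix(se_spec, X) + se_spec.noise_variance * np.eye(15)
        Ks = kernel_matrix(se_spec, X, Xs)
        mean = Ks.T @ np.linalg.solve(Ky, y)
        cov = kernel_matrix(se_spec, Xs) - Ks.T @ np.linalg.solve(Ky, Ks)
        m = Xs.size
        assert np.allclose(post.mean_f, mean, atol=1e-8)
        assert np.allclose(post.cov_blocks[:m, :m], cov, atol=1e-8)

    def test_mean_derivatives_match_finite_differences(self, synthetic_dataset):
        series = synthetic_dataset.timeseries
        spec = optimize_hyperparameters(
            series, CovarianceSpec.default("squared_exponential"), n_restarts=1, seed=1
        )
        grid = np.linspace(series.times[0], series.times[-1], 600)
        post = joint_posterior(spec, series, grid, include_covariance=False)
        h = grid[1] - grid[0]
        fd_g = (post.mean_f[2:] - post.mean_f[:-2]) / (2 * h)
        fd_h = (post.mean_g[2:] - post.mean_g[:-2]) / (2 * h)
        scale_g = np.abs(post.mean_g[1:-1]).max()
        scale_h = np.abs(post.mean_h[1:-1]).max()
        assert np.allclose(post.mean_g[1:-1], fd_g, atol=1e-3 * scale_g)
        assert np.allclose(post.mean_h[1:-1], fd_h, atol=2e-3 * scale_h)

    def test_posterior_variance_never_exceeds_prior(self, rng, se_spec):
        X = np.sort(rng.uniform(0, 10, 20))
        y = rng.normal(0, 1, 20)
        post = joint_posterior(se_spec, TimeSeries(X, y), X)
        prior = np.diag(kernel_matrix(se_spec, X))
        assert np.all(post.var_f <= prior + 1e-10)

    def test_pooled_replicates_need_no_special_casing(self, se_spec):
        t = np.repeat(np.linspace(0, 5, 6), 3)
        rng = np.random.default_rng(0)
        y = 0.3 * t + rng.normal(0, 0.1, t.size)
        post = joint_posterior(se_spec, TimeSeries(t, y), np.unique(t))
        assert np.all(np.isfinite(post.mean_f))
        assert np.all(np.isfinite(post.cov_blocks))

    def test_matern_posterior_has_no_second_derivative(self, small_series):
        spec = CovarianceSpec.default("matern_5_2", [0.0, -0.5, -2.0])
        post = joint_posterior(spec, small_series, small_series.times)
        assert post.mean_h is None
        assert post.mean_g is not None
        with pytest.raises(ValueError):
            joint_posterior(spec, small_series, small_series.times, max_order=2)


@pytest.fixture(scope="module")
def post():
    rng = np.random.default_rng(8)
    X = np.sort(rng.uniform(0, 10, 25))
    y = np.sin(0.8 * X) + rng.normal(0, 0.1, 25)
    spec = CovarianceSpec.default("squared_exponential", [0.0, -0.5, -2.0])
    return joint_posterior(spec, TimeSeries(X, y), np.linspace(1, 9, 12))


class TestSampling:
    def test_sample_mean_converges_to_posterior_mean(self, post):
        s = sample_posterior(post, 10_000, seed=1)
        se = np.sqrt(post.var_f / 10_000)
        assert np.all(np.abs(s[:, 0, :].mean(axis=0) - post.mean_f) <= 3 * se + 1e-12)

    def test_sample_variance_matches_derivative_error_bars(self, post):
        """Empirical variance of g samples reproduces the var_g diagonal."""
        s = sample_posterior(post, 10_000, seed=2)
        emp = s[:, 1, :].var(axis=0)
        assert np.allclose(emp, post.var_g, rtol=0.2)

    def test_sampling_reproducible(self, post):
        a = sample_posterior(post, 1, seed=3)
        b = sample_posterior(post, 1, seed=3)
        assert np.array_equal(a, b)


def test_two_sd_band_coverage_on_gp_draws():
    """The true latent function sits inside +/-2 sd at >=90% of points."""
    true = CovarianceSpec.default("squared_exponential", [0.0, -0.5, -2.0])
    n = 40
    inside = total = 0
    for seed in range(50):
        rng = np.random.default_rng(1000 + seed)
        X = np.sort(rng.uniform(0, 10, n))
        K = kernel_matrix(true, X)
        f = rng.multivariate_normal(np.zeros(n), K + 1e-10 * np.eye(n))
        y = f + rng.normal(0, np.sqrt(true.noise_variance), n)
        post = joint_posterior(true, TimeSeries(X, y), X)
        sd = np.sqrt(post.var_f)
        inside += np.sum(np.abs(post.mean_f - f) <= 2 * sd)
        total += n
    assert inside / total >= 0.90
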