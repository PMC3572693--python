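"""Full-conditional correctness of the Gibbs / Metropolis-within-Gibbs engine."""

import numpy as np
import pytest
from scipy import stats

from critwin.sampler import (McmcConfig, PriorSpec, _mvn_from_precision,
                             corr_matrix, linear_predictor, run_mcmc,
                             sample_latents, update_beta, update_phi,
                             update_sigma2, update_theta)


class TestCorrMatrix:
    def test_adjacent_week_correlation(self):
        S = corr_matrix(1.0, 5)
        assert S[0, 1] == pytest.approx(np.exp(-1.0), abs=1e-12)
        assert np.allclose(np.diag(S), 1.0)
        np.testing.assert_allclose(S, S.T)

    def test_near_common_effect_limit(self):
        S = corr_matrix(1e-4, 44)
        assert S.min() >= np.exp(-1e-4 * 43) - 1e-12
        assert S.min() >= 0.9956

    @pytest.mark.parametrize("phi", [0.001, 0.1, 1.0, 3.0])
    def test_positive_definite(self, phi):
        np.linalg.cholesky(corr_matrix(phi, 44))  # raises if not PD

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            corr_matrix(0.0, 10)
        with pytest.raises(ValueError):
            corr_matrix(1.0, 0)


class TestLinearPredictor:
    def test_null_parameters_give_half_probability(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        Z = np.random.default_rng(1).normal(size=(10, 2))
        p = linear_predictor(X, Z, np.zeros(3), np.zeros(2), probability=True)
        np.testing.assert_allclose(p, 0.5)

    def test_normal_quantile(self):
        X = np.zeros((1, 1))
        Z = np.ones((1, 1))
        p = linear_predictor(X, Z, np.zeros(1), np.array([1.6449]),
                             probability=True)
        assert p[0] == pytest.approx(0.95, abs=1e-4)

    def test_matches_naive_row_loop(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 4))
        Z = rng.normal(size=(25, 6))
        beta = rng.normal(size=4)
        theta = rng.normal(size=6)
        eta = linear_predictor(X, Z, beta, theta)
        oracle = np.array([sum(X[i, k] * beta[k] for k in range(4))
                           + sum(Z[i, j] * theta[j] for j in range(6))
                           for i in range(25)])
        np.testing.assert_allclose(eta, oracle, atol=1e-12)

    def test_nan_input_rejected(self):
        with pytest.raises(FloatingPointError):
            linear_predictor(np.array([[np.nan]]), None, np.ones(1), None)


class TestLatentSampling:
    def test_half_normal_moments_at_zero(self):
        rng = np.random.default_rng(0)
        n = 100_000
        w1 = sample_latents(np.ones(n, dtype=int), np.zeros(n), rng)
        w0 = sample_latents(np.zeros(n, dtype=int), np.zeros(n), rng)
        assert (w1 > 0).all() and (w0 <= 0).all()
        target = np.sqrt(2 / np.pi)
        se = np.sqrt(1 - 2 / np.pi) / np.sqrt(n)
        assert abs(w1.mean() - target) < 4 * se
        assert abs(w0.mean() + target) < 4 * se

    def test_far_tail_against_truncnorm_oracle(self):
        rng = np.random.default_rng(1)
        n = 50_000
        eta = np.full(n, 5.0)
        w = sample_latents(np.zeros(n, dtype=int), eta, rng)
        assert np.isfinite(w).all() and (w <= 0).all()
        oracle = stats.truncnorm(a=-np.inf, b=-5.0, loc=5.0, scale=1.0)
        assert abs(w.mean() - oracle.mean()) < 5 * oracle.std() / np.sqrt(n)

    @pytest.mark.parametrize("eta", [-40.0, 40.0])
    def test_extreme_truncation_stays_finite(self, eta):
        rng = np.random.default_rng(2)
        y = np.array([1, 0])
        w = sample_latents(y, np.array([eta, eta]), rng)
        assert np.isfinite(w).all()
        assert w[0] > 0 and w[1] <= 0


class TestMvnFromPrecision:
    def test_mean_matches_direct_solve(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(6, 6))
        P = A @ A.T + 6 * np.eye(6)
        b = rng.normal(size=6)
        draws = np.array([_mvn_from_precision(P, b, rng) for _ in range(20_000)])
        oracle_mean = np.linalg.solve(P, b)
        cov = np.linalg.inv(P)
        se = np.sqrt(np.diag(cov) / 20_000)
        assert np.all(np.abs(draws.mean(axis=0) - oracle_mean) < 5 * se)
        np.testing.assert_allclose(np.cov(draws.T), cov, atol=0.01)


class TestUpdateBeta:
    def test_flat_prior_limit_recovers_least_squares(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        w = rng.normal(size=40)
        prior = PriorSpec(beta_variance=1e10)
        draws = np.array([update_beta(w, X, None, None, prior, rng)
                          for _ in range(8_000)])
        ls = np.linalg.lstsq(X, w, rcond=None)[0]
        se = np.sqrt(np.diag(np.linalg.inv(X.T @ X)) / 8_000)
        assert np.all(np.abs(draws.mean(axis=0) - ls) < 5 * se)

    def test_no_data_returns_prior_draws(self):
        rng = np.random.default_rng(5)
        X = np.empty((0, 2))
        prior = PriorSpec(beta_variance=4.0)
        draws = np.array([update_beta(np.empty(0), X, None, None, prior, rng)
                          for _ in range(20_000)])
        assert abs(draws.std()) == pytest.approx(2.0, rel=0.05)
        assert abs(draws.mean()) < 0.05

    def test_seeded_reproducibility(self):
        rng1 = np.random.default_rng(6)
        rng2 = np.random.default_rng(6)
        X = np.random.default_rng(0).normal(size=(10, 2))
        w = np.random.default_rng(1).normal(size=10)
        d1 = update_beta(w, X, None, None, PriorSpec(), rng1)
        d2 = update_beta(w, X, None, None, PriorSpec(), rng2)
        np.testing.assert_array_equal(d1, d2)


class TestUpdateTheta:
    def test_prior_recovery_without_exposure_information(self):
        rng = np.random.default_rng(7)
        g, sigma2, phi = 3, 0.5, 1.2
        Z = np.zeros((10, g))
        X = np.zeros((10, 1))
        draws = np.array([
            update_theta(np.zeros(10), X, Z, np.zeros(1), sigma2, phi,
                         PriorSpec(), rng) for _ in range(30_000)])
        np.testing.assert_allclose(np.cov(draws.T),
                                   sigma2 * corr_matrix(phi, g), atol=0.02)
        assert np.all(np.abs(draws.mean(axis=0)) < 0.02)

    def test_posterior_mean_matches_gls_oracle(self):
        rng = np.random.default_rng(8)
        n, g = 20, 3
        X = rng.normal(size=(n, 2))
        Z = rng.normal(size=(n, g))
        beta = np.array([0.3, -0.2])
        w = rng.normal(size=n)
        sigma2, phi = 0.8, 0.9
        prior_prec = np.linalg.inv(sigma2 * corr_matrix(phi, g))
        oracle_mean = np.linalg.solve(Z.T @ Z + prior_prec,
                                      Z.T @ (w - X @ beta))
        draws = np.array([
            update_theta(w, X, Z, beta, sigma2, phi, PriorSpec(), rng)
            for _ in range(30_000)])
        cov = np.linalg.inv(Z.T @ Z + prior_prec)
        se = np.sqrt(np.diag(cov) / 30_000)
        assert np.all(np.abs(draws.mean(axis=0) - oracle_mean) < 5 * se)

    def test_vanishing_prior_variance_shrinks_to_zero(self):
        rng = np.random.default_rng(9)
        Z = rng.normal(size=(15, 2))
        X = np.ones((15, 1))
        w = rng.normal(size=15)
        draws = np.array([
            update_theta(w, X, Z, np.zeros(1), 1e-10, 1.0, PriorSpec(), rng)
            for _ in range(500)])
        assert np.abs(draws).max() < 1e-3


class TestUpdateSigma2:
    def test_zero_theta_gives_known_inverse_gamma_mean(self):
        rng = np.random.default_rng(10)
        draws = update_sigma2(np.zeros(44), 1.0, PriorSpec(), rng, size=100_000)
        # IG(3 + 22, 2): mean 2/24
        ig_sd = np.sqrt(4.0 / (24**2 * 23))
        assert abs(draws.mean() - 2 / 24) < 5 * ig_sd / np.sqrt(100_000)

    def test_prior_only_mean_is_one(self):
        rng = np.random.default_rng(11)
        draws = update_sigma2(np.empty(0), 1.0, PriorSpec(), rng, size=200_000)
        assert draws.mean() == pytest.approx(1.0, abs=0.02)


class TestUpdatePhi:
    def test_support_never_left(self):
        rng = np.random.default_rng(12)
        theta = rng.normal(0, 0.3, size=44)
        prior = PriorSpec()
        phi = 1.5
        for _ in range(500):
            phi, _ = update_phi(theta, 1.0, phi, prior, 1.5, rng)
            assert prior.phi_lower < phi < prior.phi_upper

    def test_degenerate_proposal_always_accepts(self):
        rng = np.random.default_rng(13)
        theta = rng.normal(0, 0.3, size=44)
        acc = [update_phi(theta, 1.0, 1.5, PriorSpec(), 1e-9, rng)[1]
               for _ in range(300)]
        assert np.mean(acc) > 0.99

    def test_out_of_support_state_rejected(self):
        with pytest.raises(ValueError):
            update_phi(np.zeros(3), 1.0, 5.0, PriorSpec(), 0.5,
                       np.random.default_rng(0))


class TestRunMcmc:
    def _toy(self, n=150, seed=0):
        rng = np.random.default_rng(seed)
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        Z = rng.normal(size=(n, 3))
        eta = X @ np.array([-0.3, 0.5]) + Z @ np.array([0.4, 0.0, -0.2])
        y = (rng.random(n) < stats.norm.cdf(eta)).astype(int)
        return y, X, Z

    def test_same_seed_identical_draw_streams(self):
        y, X, Z = self._toy()
        cfg = McmcConfig(n_burnin=100, n_samples=200, seed=42)
        d1 = run_mcmc(y, X, Z, PriorSpec(), cfg)
        d2 = run_mcmc(y, X, Z, PriorSpec(), cfg)
        np.testing.assert_array_equal(d1.beta, d2.beta)
        np.testing.assert_array_equal(d1.theta, d2.theta)
        np.testing.assert_array_equal(d1.phi, d2.phi)

    def test_structured_draw_constraints_and_shapes(self):
        y, X, Z = self._toy()
        cfg = McmcConfig(n_burnin=200, n_samples=600, thin=2, seed=1)
        d = run_mcmc(y, X, Z, PriorSpec(), cfg)
        assert d.beta.shape == (300, 2)
        assert d.theta.shape == (300, 3)
        assert (d.sigma2_theta > 0).all()
        assert ((d.phi > 1e-4) & (d.phi < 3)).all()
        assert 0 <= d.phi_acceptance_rate <= 1

    def test_diffuse_variants_skip_hyperparameters(self):
        y, X, Z = self._toy()
        cfg = McmcConfig(n_burnin=100, n_samples=200, seed=2)
        for model in ("trimester", "weekly_naive"):
            d = run_mcmc(y, X, Z, PriorSpec(), cfg, model=model)
            assert d.sigma2_theta is None and d.phi is None
            assert d.model_tag == model

    def test_mc_errors_reported_for_long_runs(self):
        y, X, Z = self._toy()
        cfg = McmcConfig(n_burnin=100, n_samples=500, seed=3)
        d = run_mcmc(y, X, Z, PriorSpec(), cfg,
                     beta_labels=["intercept", "x"],
                     theta_labels=["week_1", "week_2", "week_3"])
        assert set(d.mc_errors) == {"intercept", "x", "week_1", "week_2",
                                    "week_3"}
        assert all(v > 0 for v in d.mc_errors.values())
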