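import numpy as np
import pytest

from conftest import dense_nll_oracle, dense_posterior_oracle
from novatest import sim_data
from novatest.gp_core import (
    GPHyperParams,
    ParameterError,
    DegenerateInputError,
    _nll_value_grad,
    _sq_dists,
    default_init,
    fit_homoscedastic_gp,
    gp_posterior,
    negative_log_marginal_likelihood,
    rbf_kernel,
)


def random_problem(rng, n_max=50):
    n = int(rng.integers(5, n_max + 1))
    coords = rng.uniform(0, 3, size=(n, 2))
    params = GPHyperParams(
        mu_c=float(rng.normal()),
        sigma_k2=float(rng.uniform(0.1, 3.0)),
        length_scale=float(rng.uniform(0.2, 2.0)),
        sigma_n2=float(rng.uniform(0.01, 1.0)),
    )
    y = rng.normal(params.mu_c, 1.0, size=n)
    return y, coords, params


class TestRBFKernel:
    def test_zero_distance_gives_sigma_k2(self):
        a = np.array([[1.0, 2.0]])
        k = rbf_kernel(a, a, sigma_k2=2.5, length_scale=0.7)
        assert k[0, 0] == pytest.approx(2.5)

    def test_distance_equal_length_scale(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[0.8, 0.0]])
        k = rbf_kernel(a, b, sigma_k2=1.3, length_scale=0.8)
        assert k[0, 0] == pytest.approx(1.3 * np.exp(-0.5))

    def test_far_apart_vanishes(self):
        a = np.array([[0.0, 0.0]])
        b = np.array([[1e4, 0.0]])
        assert rbf_kernel(a, b, 1.0, 1.0)[0, 0] == pytest.approx(0.0, abs=1e-300)

    def test_symmetric_psd_on_self(self, rng):
        coords = rng.uniform(0, 1, size=(15, 2))
        k = rbf_kernel(coords, coords, 1.2, 0.4)
        np.testing.assert_allclose(k, k.T)
        assert np.linalg.eigvalsh(k).min() > -1e-10

    @pytest.mark.parametrize("sk2,ls", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_nonpositive_params_rejected(self, sk2, ls):
        a = np.zeros((1, 2))
        with pytest.raises(ParameterError):
            rbf_kernel(a, a, sk2, ls)


class TestNegativeLogMarginalLikelihood:
    def test_univariate_limit(self):
        # N=1, sigma_k2 -> 0: L1 -> 0.5 [(y - mu)^2/sn2 + log sn2 + log 2pi]
        y = np.array([1.7])
        coords = np.array([[0.0, 0.0]])
        params = GPHyperParams(mu_c=0.5, sigma_k2=1e-14, length_scale=1.0, sigma_n2=0.3)
        got = negative_log_marginal_likelihood(y, coords, params)
        want = 0.5 * ((1.7 - 0.5) ** 2 / 0.3 + np.log(0.3) + np.log(2 * np.pi))
        assert got == pytest.approx(want, rel=1e-6)

    def test_zero_residual_drops_quadratic_term(self, rng):
        coords = rng.uniform(0, 1, size=(6, 2))
        params = GPHyperParams(mu_c=2.0, sigma_k2=1.0, length_scale=0.5, sigma_n2=0.2)
        y = np.full(6, 2.0)
        got = negative_log_marginal_likelihood(y, coords, params)
        # remaining terms from the oracle with zero residual
        want = dense_nll_oracle(y, coords, params)
        assert got == pytest.approx(want, abs=1e-10)
        # and the quadratic contribution really is zero: shifting mu_c changes it
        assert got < negative_log_marginal_likelihood(y + 1.0, coords, params)

    def test_three_point_dense_oracle(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        y = np.array([0.3, -0.2, 1.1])
        params = GPHyperParams(mu_c=0.1, sigma_k2=0.8, length_scale=0.9, sigma_n2=0.15)
        got = negative_log_marginal_likelihood(y, coords, params)
        assert got == pytest.approx(dense_nll_oracle(y, coords, params), abs=1e-10)

    def test_oracle_agreement_random_draws(self, rng):
        for _ in range(20):
            y, coords, params = random_problem(rng)
            got = negative_log_marginal_likelihood(y, coords, params)
            assert got == pytest.approx(dense_nll_oracle(y, coords, params), abs=1e-8)


class TestGradient:
    def test_matches_central_finite_differences(self, rng):
        y, coords, params = random_problem(rng, n_max=25)
        d2 = _sq_dists(coords)
        theta = np.array(
            [params.mu_c, np.log(params.sigma_k2), np.log(params.length_scale), np.log(params.sigma_n2)]
        )
        _, grad = _nll_value_grad(theta, y, d2, True, 0.0, 1e-6)
        eps = 1e-6
        for i in range(4):
            up, dn = theta.copy(), theta.copy()
            up[i] += eps
            dn[i] -= eps
            fd = (
                _nll_value_grad(up, y, d2, True, 0.0, 1e-6)[0]
                - _nll_value_grad(dn, y, d2, True, 0.0, 1e-6)[0]
            ) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-7)


class TestFit:
    def test_returned_l1_not_worse_than_init(self, rng):
        y, coords, _ = random_problem(rng, n_max=30)
        init = default_init(y, coords)
        fitted = fit_homoscedastic_gp(y, coords, init=init, seed=0)
        assert negative_log_marginal_likelihood(y, coords, fitted) <= (
            negative_log_marginal_likelihood(y, coords, init) + 1e-9
        )

    def test_zero_variance_rejected(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(DegenerateInputError):
            fit_homoscedastic_gp(np.ones(3), coords)

    def test_length_scale_recovery(self):
        # median over replicates within a factor of 2 of truth
        true_l = 0.3
        recovered = []
        for s in range(20):
            spec = sim_data.SimSpec(
                n_spots=200,
                seed=500 + s,
                mean_fn={"kind": "gp", "sigma_k2": 1.0, "length_scale": true_l},
                noise_fn={"kind": "constant", "variance": 0.1},
            )
            coords = sim_data.make_coords(spec)
            y, _, _ = sim_data.simulate_gene(spec, coords)
            fitted = fit_homoscedastic_gp(y, coords, seed=s, n_restarts=1)
            recovered.append(fitted.length_scale)
        med = np.median(recovered)
        assert true_l / 2 <= med <= true_l * 2

    def test_white_noise_variance_decomposition(self):
        totals = []
        for s in range(10):
            rng = np.random.default_rng(60 + s)
            coords = rng.uniform(0, 1, size=(200, 2))
            y = rng.normal(0.0, 1.0, size=200)
            fitted = fit_homoscedastic_gp(y, coords, seed=s, n_restarts=1)
            totals.append((fitted.sigma_k2 + fitted.sigma_n2) / np.var(y))
        assert abs(np.median(totals) - 1.0) < 0.2


class TestPosterior:
    def test_noiseless_interpolation(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 5, size=(6, 2))  # well separated
        y = rng.normal(size=6)
        params = GPHyperParams(mu_c=0.0, sigma_k2=1.0, length_scale=0.5, sigma_n2=0.0)
        post = gp_posterior(y, coords, params)
        np.testing.assert_allclose(post.mean, y, atol=1e-4)
        np.testing.assert_allclose(post.variance(), 0.0, atol=1e-4)

    def test_prior_reversion_large_noise(self, rng):
        coords = rng.uniform(0, 1, size=(8, 2))
        y = rng.normal(size=8)
        params = GPHyperParams(mu_c=0.7, sigma_k2=1.0, length_scale=0.5, sigma_n2=1e8)
        post = gp_posterior(y, coords, params)
        np.testing.assert_allclose(post.mean, 0.7, atol=1e-5)

    def test_heldout_dense_oracle_small(self):
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 1, size=(4, 2))
        query = rng.uniform(0, 1, size=(2, 2))
        y = rng.normal(size=4)
        params = GPHyperParams(mu_c=0.3, sigma_k2=1.2, length_scale=0.6, sigma_n2=0.2)
        mean, cov = gp_posterior(y, coords, params, query)
        omean, ocov = dense_posterior_oracle(y, coords, params, query)
        np.testing.assert_allclose(mean, omean, atol=1e-8)
        np.testing.assert_allclose(cov, ocov, atol=1e-8)

    def test_posterior_variance_bounded_by_prior(self, rng):
        for _ in range(10):
            y, coords, params = random_problem(rng, n_max=30)
            query = rng.uniform(0, 3, size=(5, 2))
            _, cov = gp_posterior(y, coords, params, query)
            assert np.all(np.diag(cov) <= params.sigma_k2 * (1 + 1e-6) + 1e-10)

    def test_translation_equivariance(self, rng):
        y, coords, params = random_problem(rng, n_max=20)
        query = rng.uniform(0, 3, size=(3, 2))
        shift = np.array([13.5, -7.25])
        m1, c1 = gp_posterior(y, coords, params, query)
        m2, c2 = gp_posterior(y, coords + shift, params, query + shift)
        np.testing.assert_allclose(m1, m2, atol=1e-9)
        np.testing.assert_allclose(c1, c2, atol=1e-9)
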