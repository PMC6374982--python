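"""Variational Laplace and Bayesian model reduction against conjugate oracles."""

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from rovingdcm import (
    GaussianDensity,
    PriorSpec,
    bayesian_model_reduction,
    bayesian_parameter_average,
    reduce_prior,
    variational_laplace,
)


@pytest.fixture(scope="module")
def linear_problem():
    rng = np.random.default_rng(7)
    N, p = 50, 4
    X = rng.standard_normal((N, p))
    theta = np.array([0.5, -1.0, 0.3, 0.0])
    beta = 30.0
    y = X @ theta + rng.standard_normal(N) / np.sqrt(beta)
    prior = PriorSpec(
        GaussianDensity(np.zeros(p), np.eye(p), ("a", "b", "c", "d")),
        lambda_mean=np.log(beta),
        lambda_var=0.0,  # known noise precision: conjugate setting
    )
    return X, y, beta, prior


def _exact_evidence(X, y, beta, prior_density):
    N = y.size
    cov = np.eye(N) / beta + X @ prior_density.cov @ X.T
    return multivariate_normal(mean=X @ prior_density.mean, cov=cov).logpdf(y)


def test_vl_matches_conjugate_posterior(linear_problem):
    X, y, beta, prior = linear_problem
    res = variational_laplace(lambda T: T @ X.T, y, prior, max_iter=50, tol=1e-10)
    Pi0 = np.linalg.inv(prior.density.cov)
    Sig = np.linalg.inv(beta * X.T @ X + Pi0)
    mu = Sig @ (beta * X.T @ y)
    np.testing.assert_allclose(res.posterior.mean, mu, atol=1e-6)
    np.testing.assert_allclose(res.posterior.cov, Sig, atol=1e-6)
    assert res.free_energy == pytest.approx(_exact_evidence(X, y, beta, prior.density), abs=1e-6)


def test_vl_trajectory_monotone_and_estimates_noise(linear_problem):
    X, y, beta, prior = linear_problem
    est = PriorSpec(prior.density.copy(), lambda_mean=0.0, lambda_var=4.0)
    res = variational_laplace(lambda T: T @ X.T, y, est, max_iter=50, tol=1e-8)
    assert np.all(np.diff(res.trajectory) >= -1e-9)
    assert res.lambda_post == pytest.approx(np.log(beta), abs=0.6)


def test_vl_huge_tolerance_stops_after_one_step(linear_problem):
    X, y, _, prior = linear_problem
    res = variational_laplace(lambda T: T @ X.T, y, prior, max_iter=50, tol=np.inf)
    assert res.info["n_iter"] == 1


def test_vl_nonlinear_self_consistency(space, leadfield):
    """Noiseless model data: the fit recovers the generating parameters."""
    from rovingdcm.invert_erp import ErpFitter
    from rovingdcm.simulate import grand_mean_parameters

    fitter = ErpFitter(space, leadfield)
    truth = grand_mean_parameters(space)
    from rovingdcm.forward import predict_epochs

    clean = predict_epochs(space, truth, leadfield, dt_ms=1.0)[0]
    clean = clean - np.einsum("jct,jt->jc", clean, fitter._bmat)[..., None]
    res = fitter.fit(clean, max_iter=32, jacobian_refresh=0)
    prior_sd = np.sqrt(np.diag(fitter.base_prior().density.cov))
    free = res.info["free"]
    err = np.abs(res.posterior.mean[free] - truth[free])
    assert np.all(err <= 2 * prior_sd[free] + 1e-6)
    assert np.all(np.diff(res.trajectory) >= -1e-9)


class TestBMR:
    def test_identity_reduction(self, linear_problem):
        X, y, beta, prior = linear_problem
        res = variational_laplace(lambda T: T @ X.T, y, prior, max_iter=50, tol=1e-10)
        dF, post = bayesian_model_reduction(res.posterior, prior.density, prior.density.copy())
        assert dF == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(post.mean, res.posterior.mean, atol=1e-9)

    def test_matches_refit_evidence(self, linear_problem):
        X, y, beta, prior = linear_problem
        res = variational_laplace(lambda T: T @ X.T, y, prior, max_iter=50, tol=1e-10)
        for fixed in (["d"], ["b"], ["a", "c"]):
            rp = reduce_prior(prior.density, fixed)
            dF, _ = bayesian_model_reduction(res.posterior, prior.density, rp)
            exact = _exact_evidence(X, y, beta, rp) - _exact_evidence(X, y, beta, prior.density)
            assert dF == pytest.approx(exact, abs=1e-6)

    def test_penalty_grows_with_posterior_shift(self):
        """Fixing a parameter costs more the further its posterior moved."""
        names = ("x",)
        prior = GaussianDensity(np.zeros(1), np.eye(1), names)
        rp = reduce_prior(prior, ["x"])
        costs = []
        for mean in (0.5, 1.0, 2.0):
            post = GaussianDensity(np.array([mean]), 0.1 * np.eye(1), names)
            dF, _ = bayesian_model_reduction(post, prior, rp)
            costs.append(dF)
        assert costs[0] > costs[1] > costs[2]  # increasingly negative


class TestBPA:
    def test_identical_posteriors(self):
        g = GaussianDensity(np.array([1.0, -2.0]), np.diag([0.5, 2.0]), ("a", "b"))
        pooled = bayesian_parameter_average([g, g, g])
        np.testing.assert_allclose(pooled.mean, g.mean)
        np.testing.assert_allclose(pooled.cov, g.cov / 3.0)

    def test_symmetric_pair(self):
        a = GaussianDensity(np.array([0.0]), np.array([[1.0]]), ("x",))
        b = GaussianDensity(np.array([2.0]), np.array([[1.0]]), ("x",))
        assert bayesian_parameter_average([a, b]).mean[0] == pytest.approx(1.0)

    def test_three_unequal_variances_hand_computed(self):
        ms, vs = [1.0, 2.0, 4.0], [1.0, 0.5, 2.0]
        posts = [
            GaussianDensity(np.array([m]), np.array([[v]]), ("x",))
            for m, v in zip(ms, vs)
        ]
        pooled = bayesian_parameter_average(posts)
        prec = sum(1 / v for v in vs)
        expect = sum(m / v for m, v in zip(ms, vs)) / prec
        assert pooled.mean[0] == pytest.approx(expect)
        assert pooled.cov[0, 0] == pytest.approx(1 / prec)

    def test_order_invariance(self, rng):
        posts = [
            GaussianDensity(rng.standard_normal(3), np.diag(rng.uniform(0.1, 2.0, 3)), ("a", "b", "c"))
            for _ in range(5)
        ]
        p1 = bayesian_parameter_average(posts)
        p2 = bayesian_parameter_average(posts[::-1])
        np.testing.assert_allclose(p1.mean, p2.mean, atol=1e-12)
        np.testing.assert_allclose(p1.cov, p2.cov, atol=1e-12)
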