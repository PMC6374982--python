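"""Variational Laplace: Gaussian-posterior model inversion by free-energy ascent.

The generative model is y = h(theta) + eps with eps i.i.d. Gaussian whose
log-precision lambda carries a Gaussian hyperprior, and a Gaussian prior over
theta.  The scheme maximises the Laplace free energy

    F = -1/2 exp(lambda) ||y - h(theta)||^2 + N/2 (lambda - log 2 pi)
        - 1/2 (theta - mu0)' Pi0 (theta - mu0)
        + 1/2 log det(Sigma Pi0) - (lambda - lambda0)^2 / (2 v_lambda)

by Gauss-Newton updates on theta (with Levenberg-style step rejection, so the
trajectory of accepted steps is non-decreasing) interleaved with Newton
updates of lambda.  Sensitivities dh/dtheta come from batched forward
differences, so a predictor that integrates many parameter vectors at once
makes the dominant cost one batched call per iteration.

For a linear predictor and fixed lambda the converged posterior equals the
conjugate closed form and F equals the exact log evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

LOG2PI = float(np.log(2.0 * np.pi))

#: Prior variances at or below this are treated as "parameter fixed".
FIXED_VARIANCE_FLOOR = 1e-6

#: Near-zero variance used when a reduced model fixes a parameter group.
REDUCED_VARIANCE = 1e-8


@dataclass
class GaussianDensity:
    """Multivariate Gaussian over a named parameter vector."""

    mean: np.ndarray
    cov: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        p = self.mean.size
        if self.cov.shape != (p, p):
            raise ValueError("covariance shape does not match mean")
        if len(self.names) != p:
            raise ValueError("names must match the parameter dimension")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        self.cov = 0.5 * (self.cov + self.cov.T)

    @property
    def size(self) -> int:
        return self.mean.size

    def index(self, name: str) -> int:
        return self.names.index(name)

    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.cov)

    def marginal_sd(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def copy(self) -> "GaussianDensity":
        return GaussianDensity(self.mean.copy(), self.cov.copy(), self.names)

    @classmethod
    def diagonal(cls, mean: np.ndarray, variances: np.ndarray, names) -> "GaussianDensity":
        return cls(np.asarray(mean, float), np.diag(np.asarray(variances, float)), tuple(names))


@dataclass
class PriorSpec:
    """Parameter prior plus the hyperprior on log noise precision."""

    density: GaussianDensity
    lambda_mean: float = 4.0
    lambda_var: float = 1.0  # 0 = noise precision fixed at exp(lambda_mean)

    def copy(self) -> "PriorSpec":
        return PriorSpec(self.density.copy(), self.lambda_mean, self.lambda_var)


@dataclass
class InversionResult:
    posterior: GaussianDensity
    free_energy: float
    trajectory: np.ndarray  # accepted-step free energies (non-decreasing)
    lambda_post: float
    predicted: np.ndarray | None = None  # model prediction of the fitted data
    info: dict = field(default_factory=dict)


def _logdet(a: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(a)
    if sign <= 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    return float(ld)


def variational_laplace(
    predictor: Callable[[np.ndarray], np.ndarray],
    data: np.ndarray,
    priors: PriorSpec,
    max_iter: int = 32,
    tol: float = 1e-2,
    fd_step: float = 1e-3,
    jacobian_refresh: int = 0,
) -> InversionResult:
    """Fit ``data = predictor(theta) + noise`` by variational Laplace.

    ``predictor`` maps a (B, P) batch of parameter vectors to (B, N)
    predictions.  Parameters whose prior variance is at the fixed floor are
    pinned to their prior mean and excluded from the search (their posterior
    equals their prior).  ``jacobian_refresh > 0`` recomputes the sensitivity
    matrix only on the first that many iterations (quasi-Newton thereafter);
    0 recomputes every iteration.

    Returns a posterior over the full parameter vector with a non-decreasing
    accepted free-energy trajectory; converged when the free-energy gain of
    an accepted step falls below ``tol``.
    """
    y = np.asarray(data, dtype=float).ravel()
    if not np.all(np.isfinite(y)):
        raise ValueError("data must be finite")
    N = y.size
    mu0 = priors.density.mean
    C0 = priors.density.cov
    names = priors.density.names
    P = mu0.size

    prior_var = np.diag(C0)
    free = np.where(prior_var > FIXED_VARIANCE_FLOOR)[0]
    if free.size == 0:
        raise ValueError("no free parameters")
    C0f = C0[np.ix_(free, free)]
    Pi0 = np.linalg.inv(C0f)
    ld_Pi0 = -_logdet(C0f)

    lam = float(priors.lambda_mean)
    lam0, vlam = float(priors.lambda_mean), float(priors.lambda_var)

    theta = mu0.copy()

    def predict_one(th: np.ndarray) -> np.ndarray:
        return np.asarray(predictor(th[None, :])).reshape(1, -1)[0]

    def jacobian(th: np.ndarray, h0: np.ndarray) -> np.ndarray:
        batch = np.repeat(th[None, :], free.size, axis=0)
        batch[np.arange(free.size), free] += fd_step
        H = np.asarray(predictor(batch)).reshape(free.size, -1)
        return (H - h0[None, :]).T / fd_step  # (N, n_free)

    def lambda_update(lam, E):
        if vlam <= 0:
            return lam0
        for _ in range(8):
            g = 0.5 * N - 0.5 * np.exp(lam) * E - (lam - lam0) / vlam
            h = -0.5 * np.exp(lam) * E - 1.0 / vlam
            step = np.clip(-g / h, -4.0, 4.0)
            lam = lam + step
            if abs(step) < 1e-6:
                break
        return float(lam)

    def free_energy(e, dth_f, Sigf, lam):
        F = (
            -0.5 * np.exp(lam) * float(e @ e)
            + 0.5 * N * (lam - LOG2PI)
            - 0.5 * float(dth_f @ Pi0 @ dth_f)
            + 0.5 * (_logdet(Sigf) + ld_Pi0)
        )
        if vlam > 0:
            F -= 0.5 * (lam - lam0) ** 2 / vlam
        return float(F)

    h = predict_one(theta)
    if not np.all(np.isfinite(h)):
        raise FloatingPointError("non-finite prediction at the prior mean")
    e = y - h
    J = jacobian(theta, h)
    ridge = 1e-6
    JtJ = J.T @ J
    lam = lambda_update(lam, float(e @ e))
    Pf = np.exp(lam) * JtJ + Pi0
    Sigf = np.linalg.inv(Pf + ridge * np.eye(free.size))
    F = free_energy(e, theta[free] - mu0[free], Sigf, lam)
    traj = [F]

    levenberg = 0.0  # additional damping, adapted on rejection
    for it in range(max_iter):
        if jacobian_refresh == 0 or it < jacobian_refresh:
            J = jacobian(theta, h)
            JtJ = J.T @ J
        g = np.exp(lam) * (J.T @ e) - Pi0 @ (theta[free] - mu0[free])
        A = np.exp(lam) * JtJ + Pi0
        accepted = False
        for _ in range(8):
            try:
                step = np.linalg.solve(
                    A + (ridge + levenberg) * np.eye(free.size), g
                )
            except np.linalg.LinAlgError:
                levenberg = max(4 * levenberg, 1.0)
                continue
            cand = theta.copy()
            cand[free] = theta[free] + step
            try:
                h_c = predict_one(cand)
            except FloatingPointError:
                levenberg = max(4 * levenberg, 1.0)
                continue
            if not np.all(np.isfinite(h_c)):
                levenberg = max(4 * levenberg, 1.0)
                continue
            e_c = y - h_c
            lam_c = lambda_update(lam, float(e_c @ e_c))
            Pf_c = np.exp(lam_c) * JtJ + Pi0
            try:
                Sig_c = np.linalg.inv(Pf_c + ridge * np.eye(free.size))
                F_c = free_energy(e_c, cand[free] - mu0[free], Sig_c, lam_c)
            except np.linalg.LinAlgError:
                levenberg = max(4 * levenberg, 1.0)
                continue
            if F_c >= F - 1e-12:
                accepted = True
                break
            levenberg = max(4 * levenberg, 0.25)
        if not accepted:
            break
        gain = F_c - F
        theta, h, e, lam, F, Sigf = cand, h_c, e_c, lam_c, F_c, Sig_c
        traj.append(F)
        levenberg = levenberg / 4 if levenberg > 1e-8 else 0.0
        if gain < tol:
            break

    cov = C0.copy()
    cov[np.ix_(free, free)] = Sigf
    fixed = np.setdiff1d(np.arange(P), free)
    cov[np.ix_(free, fixed)] = 0.0
    cov[np.ix_(fixed, free)] = 0.0
    posterior = GaussianDensity(theta, cov, names)
    return InversionResult(
        posterior=posterior,
        free_energy=float(F),
        trajectory=np.asarray(traj),
        lambda_post=float(lam),
        predicted=h,
        info={"n_iter": len(traj) - 1, "free": free},
    )
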