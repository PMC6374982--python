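"""Bayesian model reduction and Bayesian parameter averaging.

BMR scores a reduced model -- same likelihood, changed prior -- from a full
model's fit alone.  With Gaussian prior p0 = N(m0, C0), posterior
q = N(m, C) and reduced prior pr = N(mr0, Cr0), the reduced posterior and
log-evidence change are closed form:

    Pr  = P + Pr0 - P0                  (precisions)
    mr  = Pr^-1 (P m + Pr0 mr0 - P0 m0)
    dF  = 1/2 [ log|P| + log|Pr0| - log|P0| - log|Pr| ]
        + 1/2 [ mr' Pr mr - m' P m - mr0' Pr0 mr0 + m0' P0 m0 ]

Fixing a parameter group means shrinking its prior variance to a near-zero
floor (1e-8) so all densities stay proper.
"""

from __future__ import annotations

import numpy as np

from .vl import GaussianDensity, REDUCED_VARIANCE


def _logdet(a: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(a)
    if sign <= 0:
        raise np.linalg.LinAlgError("matrix not positive definite in BMR")
    return float(ld)


def bayesian_model_reduction(
    posterior: GaussianDensity,
    prior: GaussianDensity,
    reduced_prior: GaussianDensity,
) -> tuple[float, GaussianDensity]:
    """Evidence change and posterior of a reduced model (no refitting).

    All three densities must share the same parameter names.  Returns
    (delta log-evidence in nats, reduced posterior).
    """
    if not (posterior.names == prior.names == reduced_prior.names):
        raise ValueError("densities must share an index map")
    P = posterior.precision()
    P0 = prior.precision()
    Pr0 = reduced_prior.precision()
    m, m0, mr0 = posterior.mean, prior.mean, reduced_prior.mean

    Pr = P + Pr0 - P0
    Pr = 0.5 * (Pr + Pr.T)
    Cr = np.linalg.inv(Pr)
    mr = Cr @ (P @ m + Pr0 @ mr0 - P0 @ m0)
    dF = 0.5 * (_logdet(P) + _logdet(Pr0) - _logdet(P0) - _logdet(Pr)) + 0.5 * (
        float(mr @ Pr @ mr)
        - float(m @ P @ m)
        - float(mr0 @ Pr0 @ mr0)
        + float(m0 @ P0 @ m0)
    )
    return float(dF), GaussianDensity(mr, 0.5 * (Cr + Cr.T), posterior.names)


def reduce_prior(
    prior: GaussianDensity,
    fixed_names: list[str] | tuple[str, ...] | np.ndarray,
    variance: float = REDUCED_VARIANCE,
    fixed_mean: float | None = None,
) -> GaussianDensity:
    """Reduced prior pinning the named parameters.

    Pinned entries get near-zero variance at their prior mean, or at
    ``fixed_mean`` when given (e.g. 0 to switch a modulation off even under
    empirical priors with nonzero means).
    """
    fixed = list(fixed_names)
    if fixed and isinstance(fixed[0], str):
        idx = np.array([prior.index(n) for n in fixed], dtype=int)
    else:
        idx = np.asarray(fixed, dtype=int)
    cov = prior.cov.copy()
    cov[idx, :] = 0.0
    cov[:, idx] = 0.0
    cov[idx, idx] = variance
    mean = prior.mean.copy()
    if fixed_mean is not None:
        mean[idx] = fixed_mean
    return GaussianDensity(mean, cov, prior.names)


def bayesian_parameter_average(posteriors: list[GaussianDensity]) -> GaussianDensity:
    """Precision-weighted pooling of posteriors over a shared index map."""
    if not posteriors:
        raise ValueError("need at least one posterior")
    names = posteriors[0].names
    if any(p.names != names for p in posteriors):
        raise ValueError("posteriors must share an index map")
    Ps = [p.precision() for p in posteriors]
    pooled_P = np.sum(Ps, axis=0)
    try:
        pooled_C = np.linalg.inv(pooled_P)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular pooled precision in BPA") from err
    pooled_m = pooled_C @ np.sum([Pi @ p.mean for Pi, p in zip(Ps, posteriors)], axis=0)
    return GaussianDensity(pooled_m, 0.5 * (pooled_C + pooled_C.T), names)
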