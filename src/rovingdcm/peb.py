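"""Parametric empirical Bayes: group-level GLM over session posteriors.

The hierarchical model explains each session's first-level parameters as

    theta_i = mu0 + (x_i' kron I_p) beta + zeta_i,   zeta_i ~ N(0, Gamma)

where x_i is the session's row of the design matrix (group mean, ketamine
dose code 0/1/2, per-subject indicators), beta are second-level effects with
zero-mean Gaussian priors, and Gamma = exp(-gamma) * (first-level prior
covariance over the included fields) is the between-session covariance with
a scalar log-precision hyperparameter.

Because every density is Gaussian, the session-evidence change induced by
moving the session's prior mean (a Bayesian-model-reduction identity) is an
exact quadratic in beta, so for fixed gamma the beta posterior and the
second-level free energy are closed form; gamma (and a scale on the
subject-block prior) are optimised by scalar search on the free energy.
Second-level model comparison fixes ketamine-effect entries via BMR on the
ketamine block of the beta posterior (the prior is block-diagonal across
regressors, so the block marginal is sufficient).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bmr import bayesian_model_reduction, reduce_prior
from .cohort import Cohort
from .modelspace import SecondLevelModel
from .params import ParameterSpace
from .vl import FIXED_VARIANCE_FLOOR, GaussianDensity, REDUCED_VARIANCE

#: Second-level prior variance = first-level prior variance / this factor.
BETA_PRIOR_SHRINK = 16.0


@dataclass
class DesignMatrix:
    """Sessions x regressors design with named columns."""

    X: np.ndarray
    regressors: tuple[str, ...]
    rows: tuple  # (subject_id, session) per row

    def __post_init__(self) -> None:
        if self.X.shape != (len(self.rows), len(self.regressors)):
            raise ValueError("design shape mismatch")
        ket = self.X[:, self.regressors.index("ketamine")]
        if not np.all(np.isin(ket, (0, 1, 2))):
            raise ValueError("ketamine column entries must be 0, 1 or 2")

    @property
    def n_sessions(self) -> int:
        return self.X.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.regressors.index(name)]


def build_design_matrix(cohort: Cohort, rows: list | None = None) -> DesignMatrix:
    """One row per session: group mean, dose-coded ketamine, subject block.

    ``rows`` optionally fixes the session order as (subject_id, session)
    pairs (e.g. to match a simulated session list); default order is
    subject-major with placebo before ketamine.  Every subject must
    contribute exactly both sessions.
    """
    by_id = {s.subject_id: s for s in cohort.subjects}
    if rows is None:
        rows = [(s.subject_id, sess) for s in cohort.subjects for sess in ("placebo", "ketamine")]
    counts: dict[str, set] = {}
    for sid, sess in rows:
        if sid not in by_id:
            raise KeyError(f"unknown subject {sid}")
        counts.setdefault(sid, set()).add(sess)
    if any(v != {"placebo", "ketamine"} for v in counts.values()) or len(counts) != len(by_id):
        raise ValueError("every subject needs exactly one placebo and one ketamine session")

    subj_ids = [s.subject_id for s in cohort.subjects]
    regressors = ["mean", "ketamine"] + [f"subject:{sid}" for sid in subj_ids]
    X = np.zeros((len(rows), len(regressors)))
    for i, (sid, sess) in enumerate(rows):
        X[i, 0] = 1.0
        X[i, 1] = 0 if sess == "placebo" else by_id[sid].dose_code
        X[i, 2 + subj_ids.index(sid)] = 1.0
    return DesignMatrix(X=X, regressors=tuple(regressors), rows=tuple(rows))


@dataclass
class PebResult:
    beta: GaussianDensity  # posterior over regressor x field effects
    beta_prior: GaussianDensity
    fields: tuple[str, ...]
    design: DesignMatrix
    free_energy: float
    gamma: float
    subject_scale: float
    info: dict = field(default_factory=dict)

    def block(self, regressor: str) -> GaussianDensity:
        """Marginal posterior over one regressor's effects."""
        idx = [i for i, n in enumerate(self.beta.names) if n.startswith(regressor + ":")]
        names = tuple(self.beta.names[i][len(regressor) + 1:] for i in idx)
        return GaussianDensity(self.beta.mean[idx], self.beta.cov[np.ix_(idx, idx)], names)

    def _block_prior(self, regressor: str) -> GaussianDensity:
        idx = [i for i, n in enumerate(self.beta.names) if n.startswith(regressor + ":")]
        names = tuple(self.beta.names[i][len(regressor) + 1:] for i in idx)
        return GaussianDensity(
            self.beta_prior.mean[idx], self.beta_prior.cov[np.ix_(idx, idx)], names
        )


def default_fields(prior: GaussianDensity, space: ParameterSpace) -> tuple[str, ...]:
    """Free first-level parameters, excluding the observation gain."""
    var = np.diag(prior.cov)
    return tuple(
        n for i, n in enumerate(prior.names)
        if var[i] > FIXED_VARIANCE_FLOOR and n != "gain"
    )


def peb_fit(
    session_posteriors: list[GaussianDensity],
    session_prior: GaussianDensity,
    design: DesignMatrix,
    space: ParameterSpace,
    fields: tuple[str, ...] | None = None,
    gamma_bounds: tuple[float, float] = (-2.0, 6.0),
    gamma_prior_var: float = 1.0,
    optimize_subject_scale: bool = True,
) -> PebResult:
    """Fit the second-level GLM; deterministic given inputs."""
    n = len(session_posteriors)
    if n != design.n_sessions:
        raise ValueError("design rows must align with session posteriors")
    if any(p.names != session_prior.names for p in session_posteriors):
        raise ValueError("session posteriors must share the prior's index map")
    if fields is None:
        fields = default_fields(session_prior, space)
    fidx = np.array([session_prior.index(f) for f in fields])
    p = fidx.size
    mu0 = session_prior.mean[fidx]
    C0 = session_prior.cov[np.ix_(fidx, fidx)]
    P0 = np.linalg.inv(C0)
    ld_P0 = -_logdet(C0)

    Pi = np.stack([np.linalg.inv(q.cov[np.ix_(fidx, fidx)]) for q in session_posteriors])
    mi = np.stack([q.mean[fidx] for q in session_posteriors])
    hi = np.einsum("ipq,iq->ip", Pi, mi) - (P0 @ mu0)[None, :]
    ld_Pi = np.array([_logdet(P) for P in Pi])

    X = design.X
    R = X.shape[1]
    ket_col = design.regressors.index("ketamine")
    subj_cols = [j for j, r in enumerate(design.regressors) if r.startswith("subject:")]

    base_beta_var = np.tile(np.diag(C0) / BETA_PRIOR_SHRINK, R)

    session_cache: dict = {}

    def session_summaries(gamma: float):
        """Per-session quadratics (A_i, g_i, c_i) and the assembled Q, b."""
        if gamma in session_cache:
            return session_cache[gamma]
        PG = np.exp(gamma) * P0  # Gamma^-1
        ld_PG = p * gamma + ld_P0
        A = np.empty((n, p, p))
        g = np.empty((n, p))
        c = np.empty(n)
        for i in range(n):
            Pr = Pi[i] + PG - P0
            Cr = np.linalg.inv(Pr)
            PGCr = PG @ Cr
            A[i] = PG - PGCr @ PG
            A[i] = 0.5 * (A[i] + A[i].T)
            g[i] = PGCr @ hi[i] - A[i] @ mu0
            mr = Cr @ (hi[i] + PG @ mu0)  # reduced posterior mean at delta = 0
            c[i] = 0.5 * (ld_Pi[i] + ld_PG - ld_P0 - _logdet(Pr)) + 0.5 * (
                float(mr @ Pr @ mr)
                - float(mi[i] @ Pi[i] @ mi[i])
                - float(mu0 @ PG @ mu0)
                + float(mu0 @ P0 @ mu0)
            )
        Q = np.einsum("ir,is,ipq->rpsq", X, X, A).reshape(R * p, R * p)
        Q = 0.5 * (Q + Q.T)
        b = np.einsum("ir,ip->rp", X, g).ravel()
        out = (float(c.sum()), Q, b)
        session_cache.clear()
        session_cache[gamma] = out
        return out

    def _beta_var(log_s: float) -> np.ndarray:
        beta_var = base_beta_var.copy()
        for j in subj_cols:
            beta_var[j * p:(j + 1) * p] *= np.exp(log_s)
        return beta_var

    def evaluate(gamma: float, log_s: float, want_cov: bool = False):
        from scipy.linalg import cho_factor, cho_solve

        csum, Q, b = session_summaries(gamma)
        beta_var = _beta_var(log_s)
        Pb = Q + np.diag(1.0 / beta_var)
        cf = cho_factor(Pb, lower=True)
        mb = cho_solve(cf, b)
        ld_Pb = 2.0 * float(np.log(np.diag(cf[0])).sum())
        F = (
            csum
            + 0.5 * float(b @ mb)
            - 0.5 * float(np.log(beta_var).sum())
            - 0.5 * ld_Pb
        )
        F -= 0.5 * gamma**2 / gamma_prior_var
        Cb = cho_solve(cf, np.eye(R * p)) if want_cov else None
        return F, mb, Cb, beta_var

    # coordinate search: gamma (between-session precision), then subject scale
    def scalar_max(fun, lo, hi, rounds=3):
        memo: dict[float, float] = {}

        def f(x):
            x = round(float(x), 6)
            if x not in memo:
                memo[x] = fun(x)
            return memo[x]

        xs = np.linspace(lo, hi, 5)
        for _ in range(rounds):
            vals = [f(x) for x in xs]
            j = int(np.argmax(vals))
            lo2 = xs[max(j - 1, 0)]
            hi2 = xs[min(j + 1, len(xs) - 1)]
            xs = np.linspace(lo2, hi2, 5)
        best = max(memo, key=memo.get)
        return float(best), memo[best]

    log_s = 0.0
    gamma, _ = scalar_max(lambda ga: evaluate(ga, log_s)[0], *gamma_bounds, rounds=3)
    if optimize_subject_scale:
        log_s, _ = scalar_max(lambda ls: evaluate(gamma, ls)[0], -3.0, 3.0, rounds=2)
        gamma, _ = scalar_max(lambda ga: evaluate(ga, log_s)[0], *gamma_bounds, rounds=2)
    F, mb, Cb, beta_var = evaluate(gamma, log_s, want_cov=True)

    names = tuple(
        f"{design.regressors[r]}:{fields[j]}" for r in range(R) for j in range(p)
    )
    beta = GaussianDensity(mb, Cb, names)
    beta_prior = GaussianDensity.diagonal(np.zeros(R * p), beta_var, names)
    return PebResult(
        beta=beta, beta_prior=beta_prior, fields=tuple(fields), design=design,
        free_energy=float(F), gamma=float(gamma), subject_scale=float(np.exp(log_s)),
        info={"ketamine_regressor": design.regressors[ket_col]},
    )


def _logdet(a: np.ndarray) -> float:
    sign, ld = np.linalg.slogdet(a)
    if sign <= 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    return float(ld)


def ketamine_effects(peb: PebResult) -> pd.DataFrame:
    """Per-field ketamine effect estimates with 95% CIs and probabilities."""
    post = peb.block("ketamine")
    sd = post.marginal_sd()
    probs = effect_probabilities(peb)
    return pd.DataFrame(
        {
            "parameter": post.names,
            "estimate": post.mean,
            "ci_low": post.mean - 1.96 * sd,
            "ci_high": post.mean + 1.96 * sd,
            "probability": [probs[n] for n in post.names],
        }
    )


def second_level_bmr(
    peb: PebResult, models: list[SecondLevelModel], space: ParameterSpace
) -> tuple[pd.DataFrame, SecondLevelModel]:
    """Score each declared model by BMR on the ketamine-effect block.

    Returns the evidence table (dF relative to the full second-level model,
    descending) and the winner; ties break toward the earlier declaration.
    """
    if not models:
        raise ValueError("empty second-level space")
    post = peb.block("ketamine")
    prior = peb._block_prior("ketamine")
    rows = []
    for m in models:
        free_names: set[str] = set()
        for tag in m.free_tags():
            idx = space.group(tag)
            free_names.update(space.names[i] for i in idx)
        fixed = [n for n in post.names if n not in free_names]
        rp = reduce_prior(prior, fixed, REDUCED_VARIANCE) if fixed else prior.copy()
        dF, _ = bayesian_model_reduction(post, prior, rp)
        rows.append({"model": m.name, "family": m.family, "dF": dF})
    table = pd.DataFrame(rows)
    order = np.argsort(-table["dF"].to_numpy(), kind="stable")
    winner = models[int(order[0])]
    table = table.iloc[order].reset_index(drop=True)
    return table, winner


def effect_probabilities(peb: PebResult) -> dict:
    """Posterior probability that each ketamine effect is nonzero.

    Computed by BMR against a point-null prior (variance 1e-8) on that entry
    alone: p = 1 / (1 + exp(dF_null)).  An entry whose posterior equals its
    prior scores 0.5.
    """
    post = peb.block("ketamine")
    prior = peb._block_prior("ketamine")
    out = {}
    for j, name in enumerate(post.names):
        # 1-D marginals suffice: the prior is diagonal so the evidence ratio
        # depends only on this entry's marginal (Savage-Dickey identity)
        q = GaussianDensity(post.mean[[j]], post.cov[[j]][:, [j]], (name,))
        p0 = GaussianDensity(prior.mean[[j]], prior.cov[[j]][:, [j]], (name,))
        pr = reduce_prior(p0, [0], REDUCED_VARIANCE)
        dF, _ = bayesian_model_reduction(q, p0, pr)
        out[name] = float(1.0 / (1.0 + np.exp(dF)))
    return out
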