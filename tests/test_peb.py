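"""Second-level design, PEB estimation, and effect probabilities."""

import numpy as np
import pytest
from scipy import integrate, stats

from rovingdcm import (
    GaussianDensity,
    build_design_matrix,
    effect_probabilities,
    generate_cohort,
    peb_fit,
)
from rovingdcm.bmr import bayesian_model_reduction, reduce_prior
from rovingdcm.peb import PebResult


class TestDesignMatrix:
    def test_default_cohort_design(self):
        cohort = generate_cohort(seed=0)
        design = build_design_matrix(cohort)
        assert design.X.shape[0] == 36
        assert np.all(design.column("mean") == 1)
        ket = design.column("ketamine")
        assert set(np.unique(ket)) <= {0, 1, 2}
        # each subject's indicator sums to exactly 2 rows
        for s in cohort.subjects:
            assert design.column(f"subject:{s.subject_id}").sum() == 2

    def test_dose_coding(self):
        cohort = generate_cohort(seed=0)
        design = build_design_matrix(cohort)
        high = next(s for s in cohort.subjects if s.dose_code == 2)
        for i, (sid, sess) in enumerate(design.rows):
            if sid == high.subject_id:
                expected = 2 if sess == "ketamine" else 0
                assert design.column("ketamine")[i] == expected

    def test_placebo_rows_code_zero(self):
        cohort = generate_cohort(seed=1)
        design = build_design_matrix(cohort)
        placebo_rows = [i for i, (_, sess) in enumerate(design.rows) if sess == "placebo"]
        assert np.all(design.column("ketamine")[placebo_rows] == 0)

    def test_missing_session_rejected(self):
        cohort = generate_cohort(n_subjects=2, seed=0)
        rows = [(cohort.subjects[0].subject_id, "placebo")] * 2 + [
            (cohort.subjects[1].subject_id, "placebo"),
            (cohort.subjects[1].subject_id, "ketamine"),
        ]
        with pytest.raises(ValueError):
            build_design_matrix(cohort, rows)


def _toy_peb(space, beta_true=0.3, target="g:lSTG:g3", n_subjects=8, post_sd=0.02, seed=0):
    """Synthetic session posteriors with an exact linear dose effect."""
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(n_subjects=n_subjects, seed=seed)
    design = build_design_matrix(cohort)
    names = tuple(f"p{i}" for i in range(4)) + (target,)
    p = len(names)
    prior = GaussianDensity(np.zeros(p), np.eye(p) * (1.0 / 16.0), names)
    posts = []
    for i, (sid, sess) in enumerate(design.rows):
        mean = np.zeros(p)
        mean[-1] = beta_true * design.column("ketamine")[i]
        posts.append(GaussianDensity(mean, np.eye(p) * post_sd**2, names))
    return posts, prior, design, cohort


def test_peb_recovers_exact_linear_effect(space):
    posts, prior, design, _ = _toy_peb(space, beta_true=0.3)
    peb = peb_fit(posts, prior, design, space, fields=prior.names)
    est = peb.block("ketamine").mean[list(prior.names).index("g:lSTG:g3")]
    assert est == pytest.approx(0.3, rel=0.05)
    # untouched parameters shrink to zero
    others = np.delete(peb.block("ketamine").mean, list(prior.names).index("g:lSTG:g3"))
    assert np.all(np.abs(others) < 0.02)


def test_peb_no_effect_shrinks_to_zero(space):
    posts, prior, design, _ = _toy_peb(space, beta_true=0.0)
    peb = peb_fit(posts, prior, design, space, fields=prior.names)
    assert np.all(np.abs(peb.block("ketamine").mean) < 0.02)
    probs = effect_probabilities(peb)
    assert max(probs.values()) < 0.95


def test_peb_alignment_invariance(space):
    posts, prior, design, cohort = _toy_peb(space, beta_true=0.25, seed=3)
    peb1 = peb_fit(posts, prior, design, space, fields=prior.names)
    perm = np.random.default_rng(0).permutation(len(posts))
    design2 = build_design_matrix(cohort, [design.rows[i] for i in perm])
    peb2 = peb_fit([posts[i] for i in perm], prior, design2, space, fields=prior.names)
    np.testing.assert_allclose(peb1.block("ketamine").mean, peb2.block("ketamine").mean, atol=1e-8)
    assert peb1.free_energy == pytest.approx(peb2.free_energy, abs=1e-6)


class TestEffectProbabilities:
    @staticmethod
    def _prob_quadrature(mean, sd, prior_var):
        """Oracle: model-evidence ratio by numeric integration.

        Evidence ratio of "effect present" vs the point null is
        E_q[pr(x)/p0(x)] with pr the near-zero-variance null prior.
        """
        q = stats.norm(mean, sd)
        p0 = stats.norm(0, np.sqrt(prior_var))
        pr = stats.norm(0, np.sqrt(1e-8))
        val, _ = integrate.quad(
            lambda x: q.pdf(x) * pr.pdf(x) / p0.pdf(x), -1e-3, 1e-3, limit=200
        )
        return 1.0 / (1.0 + val)

    @pytest.mark.parametrize("mean, sd", [(0.05, 0.05), (0.2, 0.08), (0.0, 0.3)])
    def test_matches_quadrature(self, mean, sd):
        prior_var = 1.0 / 16.0
        prior = GaussianDensity(np.zeros(1), np.array([[prior_var]]), ("x",))
        post = GaussianDensity(np.array([mean]), np.array([[sd**2]]), ("x",))
        dF, _ = bayesian_model_reduction(post, prior, reduce_prior(prior, ["x"]))
        p_impl = 1.0 / (1.0 + np.exp(dF))
        p_oracle = self._prob_quadrature(mean, sd, prior_var)
        assert p_impl == pytest.approx(p_oracle, abs=1e-4)

    def test_posterior_equal_to_prior_gives_half(self):
        prior = GaussianDensity(np.zeros(1), np.array([[0.25]]), ("x",))
        dF, _ = bayesian_model_reduction(prior, prior, reduce_prior(prior, ["x"]))
        assert 1.0 / (1.0 + np.exp(dF)) == pytest.approx(0.5, abs=1e-6)

    def test_large_effect_approaches_one(self):
        prior = GaussianDensity(np.zeros(1), np.array([[0.25]]), ("x",))
        post = GaussianDensity(np.array([1.0]), np.array([[0.01]]), ("x",))
        dF, _ = bayesian_model_reduction(post, prior, reduce_prior(prior, ["x"]))
        assert 1.0 / (1.0 + np.exp(dF)) > 0.999
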