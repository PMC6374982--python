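"""Synthetic study generator: cohort, sequences, sessions, baselines."""

import numpy as np
import pytest

from rovingdcm import (
    SensorErp,
    baseline_correct,
    generate_cohort,
    generate_ground_truth,
    generate_roving_sequence,
    simulate_session,
    simulate_study,
)
from rovingdcm.cohort import FREQUENCIES, INTER_ONSET_MS
from rovingdcm.forward import EPOCH_MS, SFREQ, predict_epochs
from rovingdcm.simulate import BASELINE_WINDOWS, ketamine_shift_vector


class TestCohort:
    def test_default_study_shape(self):
        cohort = generate_cohort(seed=0)
        assert len(cohort) == 18
        orders = [s.order for s in cohort.subjects]
        assert orders.count("ketamine-first") == 9
        assert orders.count("placebo-first") == 9
        assert cohort.n_sessions == 36
        assert sum(s.dose_code == 2 for s in cohort.subjects) == 6
        assert all(s.dose_code in (1, 2) for s in cohort.subjects)

    def test_determinism(self):
        assert generate_cohort(seed=3).subjects == generate_cohort(seed=3).subjects
        assert generate_cohort(seed=3).subjects != generate_cohort(seed=4).subjects

    def test_odd_cohort_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(n_subjects=17)


class TestRovingSequence:
    def test_sequence_invariants(self):
        seq = generate_roving_sequence(n_trains=200, seed=0)
        freqs = {f for f, _ in seq.tones}
        assert freqs <= set(FREQUENCIES)
        # consecutive trains differ in frequency
        train_freqs = []
        i = 0
        for count in seq.repeats:
            train_freqs.append(seq.tones[i][0])
            assert 2 <= count <= 36
            i += count
        assert all(a != b for a, b in zip(train_freqs, train_freqs[1:]))
        # fixed inter-onset interval
        onsets = np.array([t for _, t in seq.tones])
        np.testing.assert_allclose(np.diff(onsets), INTER_ONSET_MS)

    def test_condition_tags(self):
        seq = generate_roving_sequence(n_trains=1000, seed=1)
        assert len(seq.tags["D1"]) == 1000  # every train starts with a deviant
        assert len(seq.tags["S2"]) == 1000  # every train has >= 2 tones
        assert len(seq.tags["S36"]) == sum(c >= 36 for c in seq.repeats)
        # tagged positions carry the right within-train index
        first = seq.tags["S6"][0]
        assert seq.tones[first][0] == seq.tones[first - 5][0]


class TestBaselineCorrection:
    def _erp(self, data):
        return SensorErp(data=data, sfreq=SFREQ, window_ms=EPOCH_MS, channels=("Fz", "Cz"))

    def test_constant_signal_zeroed(self):
        erp = self._erp(np.full((2, 201), 3.7))
        for cond in BASELINE_WINDOWS:
            assert np.allclose(baseline_correct(erp, cond).data, 0.0)

    def test_d1_noop_when_prestim_zero_mean(self):
        t = EPOCH_MS[0] + np.arange(201) * 1000.0 / SFREQ
        data = np.tile(np.where(t > 0, 1.0, 0.0), (2, 1))
        out = baseline_correct(self._erp(data), "D1")
        np.testing.assert_allclose(out.data, data)

    def test_s6_subtracts_mean_of_both_window_means(self):
        t = EPOCH_MS[0] + np.arange(201) * 1000.0 / SFREQ
        data = np.zeros((2, 201))
        data[:, (t >= -100) & (t <= 0)] = 2.0
        data[:, (t >= 250) & (t <= 300)] = 4.0
        out = baseline_correct(self._erp(data), "S6")
        mid = (t > 0) & (t < 250)
        np.testing.assert_allclose(out.data[:, mid], -3.0)

    def test_unknown_condition(self):
        with pytest.raises(KeyError):
            baseline_correct(self._erp(np.zeros((2, 201))), "S99")


class TestSessionSimulation:
    def test_study_shape(self, small_study):
        _, sessions, _, _ = small_study
        assert len(sessions) == 8  # 4 subjects x 2 sessions
        for s in sessions:
            assert set(s.erps) == {"D1", "S2", "S6", "S36"}
            arr = s.stack()
            assert arr.shape == (4, 20, 201)

    def test_noiseless_session_equals_forward_prediction(self, space, leadfield):
        cohort = generate_cohort(n_subjects=2, seed=0)
        gt = generate_ground_truth(space, cohort, seed=0, dispersion=0.0, noise_sd=0.0)
        ds = simulate_session(cohort.subjects[0], "placebo", gt, leadfield, noise_seed=0)
        clean = predict_epochs(space, gt.grand_mean, leadfield)[0]
        from rovingdcm.invert_erp import baseline_matrix

        t = ds.erps["D1"].times_ms
        bm = baseline_matrix(t)
        expected = clean - np.einsum("jct,jt->jc", clean, bm)[..., None]
        np.testing.assert_allclose(ds.stack(), expected, atol=1e-12)

    def test_placebo_ketamine_differ_only_through_shift(self, space, leadfield):
        cohort = generate_cohort(n_subjects=2, seed=5)
        gt = generate_ground_truth(space, cohort, seed=5, noise_sd=0.0)
        sub = cohort.subjects[0]
        pl = gt.session_parameters(sub, "placebo")
        ke = gt.session_parameters(sub, "ketamine")
        diff = ke - pl
        nz = np.nonzero(diff)[0]
        assert set(space.names[i] for i in nz) == {
            f"g:{s}:g3" for s in ("lSTG", "rSTG", "lIFG", "rIFG")
        }
        np.testing.assert_allclose(diff[nz], sub.dose_code * np.array(
            [0.25, 0.25, -0.25, -0.25]
        ))

    def test_noise_scales_with_inverse_sqrt_trials(self, space, leadfield):
        cohort = generate_cohort(n_subjects=2, seed=2)
        gt = generate_ground_truth(space, cohort, seed=2, dispersion=0.0, noise_sd=1.0)
        sds = {}
        for counts in ({"D1": 100, "S2": 100, "S6": 100, "S36": 100},
                       {"D1": 400, "S2": 400, "S6": 400, "S36": 400}):
            resid = []
            for seed in range(10):
                ds = simulate_session(
                    cohort.subjects[0], "placebo", gt, leadfield,
                    noise_seed=seed, trial_counts=counts,
                )
                clean = simulate_session(
                    cohort.subjects[0], "placebo",
                    generate_ground_truth(space, cohort, seed=2, dispersion=0.0, noise_sd=0.0),
                    leadfield, noise_seed=seed, trial_counts=counts,
                )
                resid.append(ds.stack() - clean.stack())
            sds[counts["D1"]] = np.std(np.concatenate(resid))
        assert sds[400] == pytest.approx(sds[100] / 2.0, rel=0.1)

    def test_ketamine_shift_targets(self, space):
        v = ketamine_shift_vector(space, 0.25, 0.25, "g3")
        assert np.count_nonzero(v) == 4
        v2 = ketamine_shift_vector(space, 0.25, 0.25, "a_fwd")
        assert set(np.nonzero(v2)[0]) == set(space.group("a_fwd"))
        with pytest.raises(ValueError):
            ketamine_shift_vector(space, 0.25, 0.25, "nope")

    def test_study_determinism(self):
        a, _, _ = simulate_study(cohort=generate_cohort(4, seed=9), seed=9)
        b, _, _ = simulate_study(cohort=generate_cohort(4, seed=9), seed=9)
        np.testing.assert_array_equal(a[0].stack(), b[0].stack())
        np.testing.assert_array_equal(a[-1].stack(), b[-1].stack())
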