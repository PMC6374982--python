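"""Sensor-space statistics: pointwise tests and MMN peak comparison."""

import numpy as np
import pytest

from rovingdcm import mmn_peak_and_test, pointwise_ttest
from rovingdcm.forward import EPOCH_MS, SFREQ, SensorErp
from rovingdcm.simulate import ErpDataset
from rovingdcm.stats import mmn_difference_wave

CHANNELS = ("Fz", "Cz")
T = 201


def _erp(data):
    return SensorErp(data=np.asarray(data, float), sfreq=SFREQ, window_ms=EPOCH_MS, channels=CHANNELS)


def _times():
    return EPOCH_MS[0] + np.arange(T) * 1000.0 / SFREQ


class TestPointwise:
    def test_identical_inputs_null(self, rng):
        erps = [_erp(rng.standard_normal((2, T))) for _ in range(6)]
        res = pointwise_ttest(erps, [e.copy() for e in erps])
        assert np.all(res.t == 0)
        assert not res.significant.any()

    def test_constructed_offset_flagged_exactly(self, rng):
        t = _times()
        window = (t >= 100) & (t <= 200)
        a, b = [], []
        for _ in range(10):
            base = 1e-4 * rng.standard_normal((2, T))
            shifted = base.copy()
            shifted[:, window] += 1.0
            a.append(_erp(shifted))
            b.append(_erp(base))
        res = pointwise_ttest(a, b)
        sel = (res.times_ms >= 100) & (res.times_ms <= 200)
        assert res.significant[sel].all()
        assert not res.significant[~sel].any()

    def test_zero_alpha_never_flags(self, rng):
        a = [_erp(rng.standard_normal((2, T)) + 5) for _ in range(5)]
        b = [_erp(rng.standard_normal((2, T))) for _ in range(5)]
        res = pointwise_ttest(a, b, alpha=0.0)
        assert not res.significant.any()

    def test_flags_shrink_as_alpha_decreases(self, rng):
        a = [_erp(rng.standard_normal((2, T)) + 0.8) for _ in range(8)]
        b = [_erp(rng.standard_normal((2, T))) for _ in range(8)]
        loose = pointwise_ttest(a, b, alpha=0.05)
        tight = pointwise_ttest(a, b, alpha=0.001)
        assert set(np.where(tight.significant)[0]) <= set(np.where(loose.significant)[0])

    def test_subject_mismatch_rejected(self, rng):
        erps = [_erp(rng.standard_normal((2, T))) for _ in range(4)]
        with pytest.raises(ValueError):
            pointwise_ttest(erps, erps[:3])


def _session(subject, session, d1, s36, rng):
    base = 1e-6 * rng.standard_normal((2, T))
    erps = {
        "D1": _erp(base + d1),
        "S2": _erp(base),
        "S6": _erp(base),
        "S36": _erp(base + s36),
    }
    return ErpDataset(subject_id=subject, session=session, dose_code=0 if session == "placebo" else 1, erps=erps)


class TestMmn:
    def _bump(self, amp, latency=150.0):
        t = _times()
        wave = np.zeros((2, T))
        wave[0] = amp * np.exp(-0.5 * ((t - latency) / 20.0) ** 2)
        return wave

    def test_df_and_direction(self, rng):
        sessions = []
        for i in range(18):
            sid = f"S{i:02d}"
            sessions.append(_session(sid, "placebo", self._bump(-2.0), np.zeros((2, T)), rng))
            sessions.append(_session(sid, "ketamine", self._bump(-1.0), np.zeros((2, T)), rng))
        res = mmn_peak_and_test(sessions)
        assert res.df == 17
        assert res.t_stat > 0  # placebo peak magnitude larger
        assert np.all((res.placebo_latency_ms >= 100) & (res.placebo_latency_ms <= 200))

    def test_equal_sessions_give_zero_t(self, rng):
        sessions = []
        for i in range(5):
            sid = f"S{i:02d}"
            sessions.append(_session(sid, "placebo", self._bump(-1.0), np.zeros((2, T)), rng))
            sessions.append(
                ErpDataset(sid, "ketamine", 1, sessions[-1].erps)
            )
        res = mmn_peak_and_test(sessions)
        assert res.t_stat == 0.0

    def test_difference_wave_common_signal_invariance(self, rng):
        common = rng.standard_normal((2, T))
        s1 = _session("S00", "placebo", self._bump(-1.0), np.zeros((2, T)), rng)
        s2 = _session("S00", "placebo", self._bump(-1.0) + common, common, rng)
        # sessions built from different noise bases: rebuild with same base
        d1 = mmn_difference_wave(s1)
        erps = {c: _erp(s1.erps[c].data + common) for c in s1.erps}
        s3 = ErpDataset("S00", "placebo", 0, erps)
        np.testing.assert_allclose(mmn_difference_wave(s3), d1, atol=1e-12)

    def test_missing_session_rejected(self, rng):
        sessions = [_session("S00", "placebo", self._bump(-1.0), np.zeros((2, T)), rng)]
        with pytest.raises(ValueError):
            mmn_peak_and_test(sessions)
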