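"""Sensor-space statistics: pointwise Bonferroni t-tests and the MMN peak test.

Deviance (D1 vs S36) and repetition (S36 vs S2) effects are tested timepoint
by timepoint at the frontocentral electrode with paired t-tests across
subjects, Bonferroni-corrected for the number of timepoints in the tested
window.  The mismatch negativity is summarised per subject and session as
the most negative deflection of the D1 - S36 difference wave at Fz within a
search window around 150 ms, and placebo vs ketamine peak magnitudes are
compared with a paired t-test (df = n_subjects - 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .forward import SensorErp
from .simulate import ErpDataset

#: Frontocentral channel of the analyses.
MMN_CHANNEL = "Fz"
#: Search window (ms) for the difference-wave peak "around 150 ms".
MMN_SEARCH_WINDOW = (100.0, 200.0)
#: Window tested by the pointwise comparisons.
TEST_WINDOW = (0.0, 300.0)


@dataclass
class PointwiseTestResult:
    comparison: str
    channel: str
    times_ms: np.ndarray  # timepoints inside the tested window
    t: np.ndarray
    significant: np.ndarray  # Bonferroni-corrected flags
    alpha: float
    n_tests: int

    def significant_spans_ms(self) -> list[tuple[float, float]]:
        """Contiguous significant intervals, as (start, end) in ms."""
        spans = []
        sig = self.significant
        i = 0
        while i < sig.size:
            if sig[i]:
                j = i
                while j + 1 < sig.size and sig[j + 1]:
                    j += 1
                spans.append((float(self.times_ms[i]), float(self.times_ms[j])))
                i = j + 1
            else:
                i += 1
        return spans


def _stack_channel(erps: list[SensorErp], channel: str) -> np.ndarray:
    return np.stack([e.channel(channel) for e in erps])


def pointwise_ttest(
    erps_a: list[SensorErp],
    erps_b: list[SensorErp],
    window: tuple[float, float] = TEST_WINDOW,
    alpha: float = 0.05,
    channel: str = MMN_CHANNEL,
    comparison: str = "",
) -> PointwiseTestResult:
    """Paired t-test per timepoint across subjects, Bonferroni-corrected.

    ``erps_a[k]`` and ``erps_b[k]`` must belong to the same subject.
    """
    if len(erps_a) != len(erps_b):
        raise ValueError("conditions must have the same subjects")
    if len(erps_a) < 2:
        raise ValueError("need at least two subjects")
    t_axis = erps_a[0].times_ms
    sel = (t_axis >= window[0] - 1e-9) & (t_axis <= window[1] + 1e-9)
    if not sel.any():
        raise ValueError("test window outside the epoch")
    a = _stack_channel(erps_a, channel)[:, sel]
    b = _stack_channel(erps_b, channel)[:, sel]
    n_tests = int(sel.sum())
    res = sps.ttest_rel(a, b, axis=0)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    tvals = np.where(np.isnan(res.statistic), 0.0, res.statistic)
    flags = pvals < (alpha / n_tests) if alpha > 0 else np.zeros(n_tests, bool)
    return PointwiseTestResult(
        comparison=comparison or "a-vs-b",
        channel=channel,
        times_ms=t_axis[sel].copy(),
        t=tvals,
        significant=np.asarray(flags, bool),
        alpha=alpha,
        n_tests=n_tests,
    )


@dataclass
class MmnSummary:
    subjects: tuple[str, ...]
    placebo_peak: np.ndarray  # most negative deflection, per subject
    ketamine_peak: np.ndarray
    placebo_latency_ms: np.ndarray
    ketamine_latency_ms: np.ndarray
    t_stat: float  # paired t on |placebo| vs |ketamine| peak magnitudes
    df: int
    p_value: float
    channel: str = MMN_CHANNEL
    window: tuple[float, float] = MMN_SEARCH_WINDOW


def mmn_difference_wave(session: ErpDataset, channel: str = MMN_CHANNEL) -> np.ndarray:
    """D1 - S36 difference waveform at the given channel."""
    return session.erps["D1"].channel(channel) - session.erps["S36"].channel(channel)


def mmn_peak_and_test(
    sessions: list[ErpDataset],
    channel: str = MMN_CHANNEL,
    window: tuple[float, float] = MMN_SEARCH_WINDOW,
) -> MmnSummary:
    """Extract per-session MMN peaks and test placebo vs ketamine.

    A positive t statistic means larger placebo peak magnitude, i.e. MMN
    attenuation by ketamine.
    """
    by_subject: dict[str, dict[str, ErpDataset]] = {}
    for s in sessions:
        by_subject.setdefault(s.subject_id, {})[s.session] = s
    subjects = sorted(by_subject)
    for sid in subjects:
        if set(by_subject[sid]) != {"placebo", "ketamine"}:
            raise ValueError(f"subject {sid} lacks one of the two sessions")
    t_axis = sessions[0].erps["D1"].times_ms
    sel = (t_axis >= window[0] - 1e-9) & (t_axis <= window[1] + 1e-9)
    peaks = {"placebo": [], "ketamine": []}
    lats = {"placebo": [], "ketamine": []}
    for sid in subjects:
        for sess in ("placebo", "ketamine"):
            d = mmn_difference_wave(by_subject[sid][sess], channel)[sel]
            j = int(np.argmin(d))
            peaks[sess].append(float(d[j]))
            lats[sess].append(float(t_axis[sel][j]))
    p = np.asarray(peaks["placebo"])
    k = np.asarray(peaks["ketamine"])
    if np.allclose(p, k):
        t_stat, p_val = 0.0, 1.0
    else:
        res = sps.ttest_rel(np.abs(p), np.abs(k))
        t_stat, p_val = float(res.statistic), float(res.pvalue)
    return MmnSummary(
        subjects=tuple(subjects),
        placebo_peak=p,
        ketamine_peak=k,
        placebo_latency_ms=np.asarray(lats["placebo"]),
        ketamine_latency_ms=np.asarray(lats["ketamine"]),
        t_stat=t_stat,
        df=len(subjects) - 1,
        p_value=p_val,
        channel=channel,
        window=window,
    )
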