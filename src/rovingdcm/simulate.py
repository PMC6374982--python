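"""Synthetic study generator: per-session, per-condition ERPs with a known
dose-graded ketamine effect on intrinsic inhibition.

The generator emulates the shape of the crossover study end to end: a
grand-mean parameter set with repetition effects expressed through the two
temporal basis functions, Gaussian between-subject dispersion on the
log-deviations, a ketamine ground truth that shifts the ii->ss inhibition
(g3) up in bilateral STG and down in bilateral IFG in proportion to the
session's dose code, white sensor noise scaled by 1/sqrt(trial count), and
the study's condition-specific baseline-correction rules.

Repetition plasticity in the grand truth is graded up the hierarchy
(strongest N-modulation in IFG): hierarchically higher areas carry the
longer-time-scale context effects, and this composition makes the
frontocentral deviant-minus-standard difference wave shrink under the
ketamine ground truth, as observed in the emulated study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort import Cohort, Subject, generate_cohort
from .conditions import CONDITIONS
from .forward import EPOCH_MS, SFREQ, SensorErp, predict_epochs
from .leadfield import LeadField, make_synthetic_leadfield
from .network import build_default_network
from .params import ParameterSpace

#: Mean trial counts entering each condition average (sets noise scaling).
DEFAULT_TRIAL_COUNTS: dict[str, int] = {"D1": 228, "S2": 209, "S6": 150, "S36": 76}

#: Between-subject dispersion (SD of Gaussian on the log-deviations).
DEFAULT_DISPERSION = 0.125

#: Ketamine effect on g3 per dose code: +delta in STG, -delta in IFG.
DEFAULT_DELTA_STG = 0.25
DEFAULT_DELTA_IFG = 0.25

#: Per-trial sensor noise SD (a.u.).  Averaged-ERP noise is this over
#: sqrt(trials), i.e. ~0.003-0.006 a.u.: clean laboratory averages, so that
#: the ground-truth structure, not measurement noise, dominates the data.
DEFAULT_NOISE_SD = 0.05

#: Grand-truth condition-modulation weights (mono, phasic) by source class.
GRAND_TRUTH_N = {"A1": (-0.1, 0.05), "STG": (-0.2, 0.1), "IFG": (-0.9, 0.3)}
GRAND_TRUTH_B_FWD = (0.2, -0.1)
GRAND_TRUTH_B_BWD = (0.1, -0.1)

#: Baseline-correction windows (ms) per condition; S6/S36 subtract the mean
#: of the two window means.
BASELINE_WINDOWS: dict[str, tuple[tuple[float, float], ...]] = {
    "D1": ((-100.0, 0.0),),
    "S2": ((250.0, 300.0),),
    "S6": ((-100.0, 0.0), (250.0, 300.0)),
    "S36": ((-100.0, 0.0), (250.0, 300.0)),
}


def grand_mean_parameters(space: ParameterSpace) -> np.ndarray:
    """The generator's grand-truth parameter vector (log-deviations)."""
    theta = space.zeros()
    net = space.network
    for e in net.forward:
        theta[space.index(f"b_fwd:{e.name}:mono")] = GRAND_TRUTH_B_FWD[0]
        theta[space.index(f"b_fwd:{e.name}:phas")] = GRAND_TRUTH_B_FWD[1]
    for e in net.backward:
        theta[space.index(f"b_bwd:{e.name}:mono")] = GRAND_TRUTH_B_BWD[0]
        theta[space.index(f"b_bwd:{e.name}:phas")] = GRAND_TRUTH_B_BWD[1]
    for s in net.source_names:
        cls = "A1" if "A1" in s else ("STG" if "STG" in s else "IFG")
        theta[space.index(f"n:{s}:mono")] = GRAND_TRUTH_N[cls][0]
        theta[space.index(f"n:{s}:phas")] = GRAND_TRUTH_N[cls][1]
    return theta


def ketamine_shift_vector(
    space: ParameterSpace,
    delta_stg: float = DEFAULT_DELTA_STG,
    delta_ifg: float = DEFAULT_DELTA_IFG,
    target: str = "g3",
) -> np.ndarray:
    """Per-unit-dose parameter shift of a ketamine session.

    The default ("g3") shifts ii->ss inhibition up by delta_stg in bilateral
    STG and down by delta_ifg in bilateral IFG.  Target "a_fwd" instead
    shifts all forward extrinsic couplings (an extrinsic control used to
    validate the second-level model comparison).
    """
    if delta_stg < 0 or delta_ifg < 0:
        raise ValueError("effect sizes must be non-negative")
    shift = space.zeros()
    if target == "g3":
        for s in ("lSTG", "rSTG"):
            shift[space.index(f"g:{s}:g3")] = delta_stg
        for s in ("lIFG", "rIFG"):
            shift[space.index(f"g:{s}:g3")] = -delta_ifg
    elif target == "a_fwd":
        for e in space.network.forward:
            shift[space.index(f"a_fwd:{e.name}")] = -delta_stg
    else:
        raise ValueError(f"unknown ketamine target {target!r}")
    return shift


@dataclass
class GroundTruth:
    """Everything the generator knows and downstream analyses must recover."""

    space: ParameterSpace
    grand_mean: np.ndarray
    subject_deviations: dict  # subject_id -> deviation vector
    ketamine_shift: np.ndarray  # per unit dose code
    noise_sd: float = DEFAULT_NOISE_SD
    dispersion: float = DEFAULT_DISPERSION

    def session_parameters(self, subject: Subject, session: str) -> np.ndarray:
        """Subject's parameter vector for one session.

        Placebo sessions get the subject's deviations only; ketamine
        sessions additionally receive the dose-scaled ketamine shift.
        """
        if subject.subject_id not in self.subject_deviations:
            raise KeyError(f"no ground truth for subject {subject.subject_id}")
        theta = self.grand_mean + self.subject_deviations[subject.subject_id]
        if session == "ketamine":
            theta = theta + subject.dose_code * self.ketamine_shift
        elif session != "placebo":
            raise ValueError(f"unknown session condition {session!r}")
        return theta


#: Parameter groups receiving between-subject dispersion (rate constants are
#: held at the prior mean; identifiability of tau from 20-channel averages is
#: poor and the study's effects live in the coupling parameters).
DISPERSED_GROUPS = ("g", "m", "a", "b", "n")


def generate_ground_truth(
    space: ParameterSpace,
    cohort: Cohort,
    seed: int = 0,
    dispersion: float = DEFAULT_DISPERSION,
    delta_stg: float = DEFAULT_DELTA_STG,
    delta_ifg: float = DEFAULT_DELTA_IFG,
    noise_sd: float = DEFAULT_NOISE_SD,
    ketamine_target: str = "g3",
) -> GroundTruth:
    """Draw per-subject deviations around the grand mean (deterministic)."""
    rng = np.random.default_rng(seed)
    free = np.concatenate([space.group(g) for g in DISPERSED_GROUPS])
    devs = {}
    for s in cohort.subjects:
        d = space.zeros()
        d[free] = dispersion * rng.standard_normal(free.size)
        devs[s.subject_id] = d
    return GroundTruth(
        space=space,
        grand_mean=grand_mean_parameters(space),
        subject_deviations=devs,
        ketamine_shift=ketamine_shift_vector(space, delta_stg, delta_ifg, ketamine_target),
        noise_sd=noise_sd,
        dispersion=dispersion,
    )


@dataclass
class ErpDataset:
    """One session's condition-average ERPs plus metadata."""

    subject_id: str
    session: str  # "placebo" | "ketamine"
    dose_code: int  # 0 for placebo
    erps: dict  # condition label -> SensorErp
    trial_counts: dict = field(default_factory=lambda: dict(DEFAULT_TRIAL_COUNTS))

    def __post_init__(self) -> None:
        missing = [c for c in CONDITIONS if c not in self.erps]
        if missing:
            raise ValueError(f"session missing conditions {missing}")
        ref = self.erps[CONDITIONS[0]]
        for c in CONDITIONS:
            e = self.erps[c]
            if e.channels != ref.channels or e.sfreq != ref.sfreq or e.window_ms != ref.window_ms:
                raise ValueError("conditions must share montage, rate and window")

    @property
    def channels(self) -> tuple[str, ...]:
        return self.erps[CONDITIONS[0]].channels

    def stack(self) -> np.ndarray:
        """(n_cond, C, T) array in canonical condition order."""
        return np.stack([self.erps[c].data for c in CONDITIONS])


def baseline_correct(erp: SensorErp, condition: str) -> SensorErp:
    """Apply the study's condition-specific baseline rule.

    D1 subtracts the mean over [-100, 0] ms; S2 over [250, 300] ms; S6 and
    S36 subtract the average of the two window means (both rules), avoiding
    the P3a contamination at the end of deviant epochs.
    """
    if condition not in BASELINE_WINDOWS:
        raise KeyError(f"unknown condition {condition!r}")
    t = erp.times_ms
    means = []
    for (t0, t1) in BASELINE_WINDOWS[condition]:
        if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
            raise ValueError(f"baseline window ({t0}, {t1}) outside epoch")
        sel = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
        means.append(erp.data[:, sel].mean(axis=1))
    offset = np.mean(means, axis=0)
    out = erp.copy()
    out.data = out.data - offset[:, None]
    return out


def _noisy_session(
    clean: np.ndarray,
    leadfield: LeadField,
    noise_sd: float,
    trial_counts: dict,
    rng: np.random.Generator,
) -> dict:
    erps = {}
    for j, c in enumerate(CONDITIONS):
        sd = noise_sd / np.sqrt(trial_counts[c])
        data = clean[j] + sd * rng.standard_normal(clean[j].shape)
        erp = SensorErp(data=data, sfreq=SFREQ, window_ms=EPOCH_MS, channels=leadfield.channels)
        erps[c] = baseline_correct(erp, c)
    return erps


def simulate_session(
    subject: Subject,
    session: str,
    ground_truth: GroundTruth,
    leadfield: LeadField,
    noise_seed: int = 0,
    trial_counts: dict | None = None,
    dt_ms: float = 0.5,
) -> ErpDataset:
    """Simulate one session (all four conditions) for one subject."""
    counts = dict(trial_counts or DEFAULT_TRIAL_COUNTS)
    theta = ground_truth.session_parameters(subject, session)
    clean = predict_epochs(ground_truth.space, theta, leadfield, dt_ms=dt_ms)[0]
    rng = np.random.default_rng(noise_seed)
    erps = _noisy_session(clean, leadfield, ground_truth.noise_sd, counts, rng)
    return ErpDataset(
        subject_id=subject.subject_id,
        session=session,
        dose_code=0 if session == "placebo" else subject.dose_code,
        erps=erps,
        trial_counts=counts,
    )


def simulate_study(
    cohort: Cohort | None = None,
    seed: int = 0,
    dispersion: float = DEFAULT_DISPERSION,
    delta_stg: float = DEFAULT_DELTA_STG,
    delta_ifg: float = DEFAULT_DELTA_IFG,
    noise_sd: float = DEFAULT_NOISE_SD,
    ketamine_target: str = "g3",
    space: ParameterSpace | None = None,
    leadfield: LeadField | None = None,
    dt_ms: float = 0.5,
) -> tuple[list[ErpDataset], GroundTruth, LeadField]:
    """Simulate the full crossover study (2 sessions per subject).

    All randomness derives from ``seed``; the forward integrations for all
    sessions are batched into a single pass per condition for speed.
    """
    if space is None:
        space = ParameterSpace(build_default_network())
    if cohort is None:
        cohort = generate_cohort(seed=seed)
    if leadfield is None:
        leadfield = make_synthetic_leadfield(network=space.network, seed=seed)
    rng = np.random.default_rng(seed)
    gt = generate_ground_truth(
        space, cohort, seed=int(rng.integers(2**31)), dispersion=dispersion,
        delta_stg=delta_stg, delta_ifg=delta_ifg, noise_sd=noise_sd,
        ketamine_target=ketamine_target,
    )
    plan = [(s, sess) for s in cohort.subjects for sess in ("placebo", "ketamine")]
    thetas = np.stack([gt.session_parameters(s, sess) for s, sess in plan])
    clean = predict_epochs(space, thetas, leadfield, dt_ms=dt_ms)  # (B, 4, C, T)
    sessions = []
    for b, (s, sess) in enumerate(plan):
        srng = np.random.default_rng(int(rng.integers(2**31)))
        erps = _noisy_session(clean[b], leadfield, gt.noise_sd, DEFAULT_TRIAL_COUNTS, srng)
        sessions.append(
            ErpDataset(
                subject_id=s.subject_id,
                session=sess,
                dose_code=0 if sess == "placebo" else s.dose_code,
                erps=erps,
            )
        )
    return sessions, gt, leadfield
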