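"""Cohort and roving-oddball stimulus-sequence generation.

The emulated study is a randomized placebo-controlled crossover: 18 subjects,
each measured in a placebo and a ketamine session, 9 subjects per infusion
order.  Two ketamine dose tiers exist (0.083 and 0.250 mg/kg/h); the dose
regressor codes placebo sessions 0 and ketamine sessions 1 (low) or 2 (high),
preserving differential effect sizes across participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

LOW_DOSE_MG_KG_H = 0.083
HIGH_DOSE_MG_KG_H = 0.250

#: Tone frequency grid, Hz.
FREQUENCIES = tuple(range(700, 1250, 50))
#: Inter-onset interval (ms) and tone duration (ms).
INTER_ONSET_MS = 400.0
TONE_DURATION_MS = 25.0
#: Range of repetitions of a tone before the frequency changes.
MIN_REPEATS, MAX_REPEATS = 2, 36


@dataclass(frozen=True)
class Subject:
    subject_id: str
    dose_mg_kg_h: float
    dose_code: int  # 1 (low) or 2 (high); the placebo session codes 0
    order: str  # "ketamine-first" | "placebo-first"


@dataclass(frozen=True)
class Cohort:
    subjects: tuple[Subject, ...]

    def __post_init__(self) -> None:
        orders = [s.order for s in self.subjects]
        n_kf = orders.count("ketamine-first")
        if n_kf * 2 != len(self.subjects):
            raise ValueError("crossover arms must be balanced")
        if any(s.dose_code not in (1, 2) for s in self.subjects):
            raise ValueError("subject dose codes must be 1 or 2")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_sessions(self) -> int:
        return 2 * len(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "dose_mg_kg_h": [s.dose_mg_kg_h for s in self.subjects],
                "dose_code": [s.dose_code for s in self.subjects],
                "order": [s.order for s in self.subjects],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Cohort":
        return cls(
            tuple(
                Subject(r.subject_id, float(r.dose_mg_kg_h), int(r.dose_code), r.order)
                for r in df.itertuples()
            )
        )


def generate_cohort(
    n_subjects: int = 18, high_dose_fraction: float = 1.0 / 3.0, seed: int = 0
) -> Cohort:
    """Deterministic-given-seed cohort with balanced crossover arms.

    Exactly ``n_subjects/2`` subjects per order arm; ``round(n * fraction)``
    subjects on the high dose tier (default 6 of 18, as in the emulated
    study's enrolment after the dose reduction).
    """
    if n_subjects % 2:
        raise ValueError("n_subjects must be even for a balanced crossover")
    rng = np.random.default_rng(seed)
    n_high = int(round(n_subjects * high_dose_fraction))
    tiers = np.array([2] * n_high + [1] * (n_subjects - n_high))
    rng.shuffle(tiers)
    orders = np.array(["ketamine-first"] * (n_subjects // 2) + ["placebo-first"] * (n_subjects // 2))
    rng.shuffle(orders)
    subjects = tuple(
        Subject(
            subject_id=f"S{i + 1:02d}",
            dose_mg_kg_h=HIGH_DOSE_MG_KG_H if tiers[i] == 2 else LOW_DOSE_MG_KG_H,
            dose_code=int(tiers[i]),
            order=str(orders[i]),
        )
        for i in range(n_subjects)
    )
    return Cohort(subjects)


@dataclass(frozen=True)
class RovingSequence:
    """Pseudorandom roving tone sequence.

    ``tones`` is a (frequency Hz, onset ms) list; ``repeats`` the per-train
    repetition counts; ``tags`` maps each condition label to the indices (into
    ``tones``) of the tone occupying that within-train position.
    """

    tones: tuple[tuple[int, float], ...]
    repeats: tuple[int, ...]
    tags: dict

    @property
    def n_trains(self) -> int:
        return len(self.repeats)


def generate_roving_sequence(n_trains: int, seed: int = 0) -> RovingSequence:
    """Generate ``n_trains`` trains of repeated tones.

    Frequencies are drawn uniformly from the 700-1200 Hz 50-Hz grid with the
    constraint that consecutive trains differ; repetition counts are uniform
    integers on [2, 36]; tones are spaced 400 ms apart.  Condition tags mark
    within-train positions 1 (D1), 2 (S2), 6 (S6) and 36 (S36) where the
    train is long enough.
    """
    if n_trains < 1:
        raise ValueError("need at least one train")
    rng = np.random.default_rng(seed)
    tones: list[tuple[int, float]] = []
    repeats: list[int] = []
    tags: dict[str, list[int]] = {"D1": [], "S2": [], "S6": [], "S36": []}
    prev_freq = None
    onset = 0.0
    for _ in range(n_trains):
        choices = [f for f in FREQUENCIES if f != prev_freq]
        freq = int(rng.choice(choices))
        count = int(rng.integers(MIN_REPEATS, MAX_REPEATS + 1))
        start = len(tones)
        for k in range(count):
            tones.append((freq, onset))
            onset += INTER_ONSET_MS
        for label, pos in (("D1", 1), ("S2", 2), ("S6", 6), ("S36", 36)):
            if count >= pos:
                tags[label].append(start + pos - 1)
        prev_freq = freq
        repeats.append(count)
    return RovingSequence(tones=tuple(tones), repeats=tuple(repeats), tags=tags)
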