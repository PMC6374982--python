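"""Roving-oddball conditions and the temporal basis functions for repetition effects.

In a roving paradigm a tone is repeated a variable number of times before its
frequency changes, so the first tone of a train is a deviant (D1) and later
repetitions are progressively better-established standards (S2, S6, S36).
Repetition-dependent changes in connectivity are expressed as a linear mixture
of two temporal basis functions over the repetition number r:

* a **monophasic decay**, maximal for the deviant and decaying with repetition,
  ``exp(-(r - 1) / lambda_m)``;
* a **phasic change**, zero at the deviant and maximal at the first standard,
  ``(r - 1) * exp(-(r - 2) / lambda_p)`` normalised to peak value 1 at r = 2.

A condition-specific modulation weight (a B or N parameter) multiplies each
basis function, and the weighted sum is added to the baseline log-coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Ordered condition labels and their repetition numbers within a train.
CONDITIONS: tuple[str, ...] = ("D1", "S2", "S6", "S36")
REPETITIONS: tuple[int, ...] = (1, 2, 6, 36)

#: Names of the two basis functions, in the order weights are stored.
BASIS_NAMES: tuple[str, str] = ("mono", "phas")


def condition_index(label: str) -> int:
    """Return the 0-based index of a condition label (D1, S2, S6, S36)."""
    try:
        return CONDITIONS.index(label)
    except ValueError:
        raise KeyError(f"unknown condition {label!r}; expected one of {CONDITIONS}") from None


@dataclass(frozen=True)
class TemporalBasisSet:
    """Two temporal basis functions evaluated on the condition grid.

    Parameters
    ----------
    lambda_mono : float
        Decay constant (in repetitions) of the monophasic basis. Default 8.
    lambda_phasic : float
        Decay constant of the phasic basis beyond its r = 2 peak. Default 2.
    """

    lambda_mono: float = 8.0
    lambda_phasic: float = 2.0
    _table: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.lambda_mono <= 0 or self.lambda_phasic <= 0:
            raise ValueError("basis decay constants must be positive")
        r = np.asarray(REPETITIONS, dtype=float)
        mono = np.exp(-(r - 1.0) / self.lambda_mono)
        phas = (r - 1.0) * np.exp(-(r - 2.0) / self.lambda_phasic)
        # normalise each to peak 1 on the condition grid (mono peaks at D1 by
        # construction; phas at S2 for any lambda_p <= 1/log(3/2) ... enforced
        # by explicit division with its r=2 value)
        phas = phas / phas[1]
        if np.argmax(phas) != 1:
            raise ValueError(
                "lambda_phasic too slow: the phasic basis must peak at S2 "
                "on the condition grid"
            )
        object.__setattr__(self, "_table", np.stack([mono, phas]))

    def values(self, cond: int | str) -> np.ndarray:
        """Return ``(monophasic, phasic)`` values for one condition."""
        i = condition_index(cond) if isinstance(cond, str) else int(cond)
        if not 0 <= i < len(CONDITIONS):
            raise KeyError(f"condition index {i} out of range 0..{len(CONDITIONS) - 1}")
        return self._table[:, i].copy()

    @property
    def table(self) -> np.ndarray:
        """(2, 4) array of basis values, rows (mono, phas) x columns (D1..S36)."""
        return self._table.copy()


def basis_values(cond: int | str, basis_set: TemporalBasisSet | None = None) -> tuple[float, float]:
    """Evaluate the (monophasic, phasic) basis pair for one condition.

    ``monophasic(D1) == 1`` and ``phasic(S2) == 1`` by peak normalisation.
    """
    bs = basis_set if basis_set is not None else TemporalBasisSet()
    v = bs.values(cond)
    return float(v[0]), float(v[1])
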