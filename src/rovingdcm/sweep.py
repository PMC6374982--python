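"""Forward characterisation of the region-specific disinhibition effect.

The winning group-level explanation of the drug effect -- opposed changes of
ii->ss inhibition at different hierarchical levels -- is characterised by
simulation: the log-scaled g3 of bilateral STG is swept from 0 to +2 while
bilateral IFG is swept from 0 to -2, and for each step the deviant-condition
source responses are recorded, both as superficial-pyramidal time courses
and as (sp, ss) state-space trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditions import TemporalBasisSet
from .forward import StimulusInput, integrate_erp
from .params import ParameterSpace


@dataclass
class SweepResult:
    """Grid of opposed g3 modulations with per-step source responses."""

    stg_offsets: np.ndarray
    ifg_offsets: np.ndarray
    times_ms: np.ndarray
    sp: np.ndarray  # (n_steps, n_sources, T); NaN rows for failed steps
    ss: np.ndarray
    source_names: tuple[str, ...]
    condition: int
    failures: dict = field(default_factory=dict)  # step index -> message

    @property
    def n_steps(self) -> int:
        return self.stg_offsets.size

    def peak_amplitude(self, source: str, population: str = "sp") -> np.ndarray:
        arr = self.sp if population == "sp" else self.ss
        j = self.source_names.index(source)
        return np.nanmax(np.abs(arr[:, j, :]), axis=1)

    def peak_latency_ms(self, source: str, population: str = "sp") -> np.ndarray:
        arr = self.sp if population == "sp" else self.ss
        j = self.source_names.index(source)
        return self.times_ms[np.nanargmax(np.abs(arr[:, j, :]), axis=1)]

    def trajectory(self, source: str, step: int) -> np.ndarray:
        """(T, 2) array of (sp, ss) samples for a state-space plot."""
        j = self.source_names.index(source)
        return np.stack([self.sp[step, j], self.ss[step, j]], axis=1)


def run_g3_sweep(
    space: ParameterSpace,
    grand_mean_params: np.ndarray,
    stg_range: tuple[float, float] = (0.0, 2.0),
    ifg_range: tuple[float, float] = (0.0, -2.0),
    n_steps: int = 9,
    condition: int = 0,
    stimulus: StimulusInput | None = None,
    basis_set: TemporalBasisSet | None = None,
    dt_ms: float = 0.5,
) -> SweepResult:
    """Simulate the opposed STG/IFG g3 modulation on an n-step grid.

    Step 0 applies zero offsets when the ranges start at 0, so it reproduces
    the unmodulated grand-mean simulation exactly.  A step whose simulation
    diverges is recorded in ``failures`` (its rows are NaN) and the
    remaining steps are retained.
    """
    if n_steps < 2:
        raise ValueError("need at least two sweep steps")
    if not (np.isfinite(stg_range).all() and np.isfinite(ifg_range).all()):
        raise ValueError("sweep ranges must be finite")
    grand_mean_params = np.asarray(grand_mean_params, dtype=float)
    stg = np.linspace(stg_range[0], stg_range[1], n_steps)
    ifg = np.linspace(ifg_range[0], ifg_range[1], n_steps)
    net = space.network
    S = net.n_sources

    times = None
    sp = ss = None
    failures: dict[int, str] = {}
    for k in range(n_steps):
        theta = grand_mean_params.copy()
        for s in net.source_names:
            if "STG" in s:
                theta[space.index(f"g:{s}:g3")] += stg[k]
            elif "IFG" in s:
                theta[space.index(f"g:{s}:g3")] += ifg[k]
        try:
            r = integrate_erp(
                space, theta, condition, stimulus=stimulus, dt_ms=dt_ms, basis_set=basis_set
            )
        except FloatingPointError as err:
            failures[k] = str(err)
            continue
        if times is None:
            times = r.times_ms
            sp = np.full((n_steps, S, times.size), np.nan)
            ss = np.full((n_steps, S, times.size), np.nan)
        sp[k] = r.v[:, 1, :]
        ss[k] = r.v[:, 0, :]
    if times is None:
        raise FloatingPointError("every sweep step diverged")
    return SweepResult(
        stg_offsets=stg,
        ifg_offsets=ifg,
        times_ms=times,
        sp=sp,
        ss=ss,
        source_names=net.source_names,
        condition=condition,
        failures=failures,
    )
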