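"""Deterministic sensor-space ERP generation from the neural model.

The chain is: exogenous stimulus bump -> fixed-step RK4 integration of the
microcircuit flow -> pyramidal depolarisation mixture -> lead-field projection
-> peristimulus epoch on the recording grid.  Everything here is
deterministic and bit-reproducible given identical inputs; measurement noise
is added by the synthetic-data generator, never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cmc import SIGMOID_SLOPE, cmc_flow, condition_operators

try:  # compiled fast path for the batched integrator
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _rk4_batched(kappa, W, msp, sp_idx, u_in, u, u_half, dt, idx_out, out):
        B, N = kappa.shape
        S = sp_idx.shape[0]
        n_steps = u.shape[0] - 1
        v = np.zeros((B, N))
        ci = np.zeros((B, N))
        kv = np.empty((4, B, N))
        ki = np.empty((4, B, N))
        vv = np.empty((B, N))
        ii = np.empty((B, N))
        s = np.empty(N)
        out_map = np.full(n_steps + 1, -1, np.int64)
        for j in range(idx_out.shape[0]):
            out_map[idx_out[j]] = j
        if out_map[0] >= 0:
            out[:, out_map[0], :] = v
        for k in range(n_steps):
            for stage in range(4):
                if stage == 0:
                    ut = u[k]
                    for b in range(B):
                        for n in range(N):
                            vv[b, n] = v[b, n]
                            ii[b, n] = ci[b, n]
                elif stage == 3:
                    ut = u[k + 1]
                    for b in range(B):
                        for n in range(N):
                            vv[b, n] = v[b, n] + dt * kv[2, b, n]
                            ii[b, n] = ci[b, n] + dt * ki[2, b, n]
                else:
                    ut = u_half[k]
                    for b in range(B):
                        for n in range(N):
                            vv[b, n] = v[b, n] + 0.5 * dt * kv[stage - 1, b, n]
                            ii[b, n] = ci[b, n] + 0.5 * dt * ki[stage - 1, b, n]
                for b in range(B):
                    for n in range(N):
                        s[n] = 1.0 / (1.0 + np.exp(-SIGMOID_SLOPE * vv[b, n])) - 0.5
                    for n in range(N):
                        acc = u_in[n] * ut
                        for m in range(N):
                            acc += W[b, n, m] * s[m]
                        kv[stage, b, n] = ii[b, n]
                        ki[stage, b, n] = (
                            kappa[b, n] * acc
                            - 2.0 * kappa[b, n] * ii[b, n]
                            - kappa[b, n] * kappa[b, n] * vv[b, n]
                        )
                    for jj in range(S):
                        p = sp_idx[jj]
                        ki[stage, b, p] += kappa[b, p] * msp[b, jj] * s[p] ** 3
            for b in range(B):
                for n in range(N):
                    v[b, n] += dt / 6.0 * (
                        kv[0, b, n] + 2.0 * kv[1, b, n] + 2.0 * kv[2, b, n] + kv[3, b, n]
                    )
                    ci[b, n] += dt / 6.0 * (
                        ki[0, b, n] + 2.0 * ki[1, b, n] + 2.0 * ki[2, b, n] + ki[3, b, n]
                    )
            if out_map[k + 1] >= 0:
                out[:, out_map[k + 1], :] = v

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is available in practice
    _HAVE_NUMBA = False
from .conditions import TemporalBasisSet
from .network import N_POP
from .params import ParameterSpace

#: Recording epoch (ms, closed interval) and sampling rate (Hz).
EPOCH_MS = (-100.0, 300.0)
SFREQ = 500.0

#: Default integration step, ms.
DEFAULT_DT_MS = 0.5

#: Pyramidal mixture projected to sensors: sp-dominant with a small dp part.
OBS_WEIGHT_SP = 1.0
OBS_WEIGHT_DP = 0.2


@dataclass(frozen=True)
class StimulusInput:
    """Gaussian bump of exogenous drive delivered to the input sources.

    The 60 ms default onset absorbs the subcortical conduction delay between
    the tone and the arrival of the volley in primary auditory cortex.
    """

    onset_ms: float = 60.0
    dispersion_ms: float = 16.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.dispersion_ms <= 0:
            raise ValueError("stimulus dispersion must be positive")
        if self.amplitude < 0:
            raise ValueError("stimulus amplitude must be non-negative")

    def waveform(self, t_ms: np.ndarray) -> np.ndarray:
        d = (np.asarray(t_ms, dtype=float) - self.onset_ms) / self.dispersion_ms
        return self.amplitude * np.exp(-0.5 * d * d)


@dataclass
class SourceResponse:
    """Per source x population depolarisation time series (0..300 ms)."""

    times_ms: np.ndarray
    v: np.ndarray  # (n_sources, 4, T)
    source_names: tuple[str, ...]

    def population(self, source: str, pop: str) -> np.ndarray:
        from .network import POPULATIONS

        si = self.source_names.index(source)
        pi = [p.value for p in POPULATIONS].index(pop)
        return self.v[si, pi]


@dataclass
class SensorErp:
    """Channels x time ERP on the recording grid.

    window_ms is the closed peristimulus interval; the montage is
    average-referenced by construction of the lead field.
    """

    data: np.ndarray  # (C, T)
    sfreq: float
    window_ms: tuple[float, float]
    channels: tuple[str, ...]
    reference: str = "average"
    times_ms: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        t0, t1 = self.window_ms
        if not t0 < t1:
            raise ValueError("epoch window start must precede end")
        n = int(round((t1 - t0) * self.sfreq / 1000.0)) + 1
        if self.data.shape != (len(self.channels), n):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channels)} channels x {n} samples"
            )
        self.times_ms = t0 + np.arange(n) * 1000.0 / self.sfreq

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    def copy(self) -> "SensorErp":
        return SensorErp(self.data.copy(), self.sfreq, self.window_ms, self.channels, self.reference)


def integrate_states(
    space: ParameterSpace,
    theta: np.ndarray,
    cond: int | str,
    stimulus: StimulusInput,
    t_out_ms: np.ndarray,
    dt_ms: float = DEFAULT_DT_MS,
    basis_set: TemporalBasisSet | None = None,
) -> np.ndarray:
    """Batched fixed-step RK4 integration of the microcircuit flow.

    theta may be (P,) or (B, P); returns depolarisations (B, T, N) sampled at
    ``t_out_ms`` (which must lie on the integration grid).  Integration starts
    from the resting (all-zero) state at t = 0.  Raises FloatingPointError if
    the state diverges, naming the worst source/population.
    """
    if dt_ms > 1.0 + 1e-12:
        raise ValueError("integration step must be <= 1 ms")
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    ops = condition_operators(space, theta, cond, basis_set)
    B, N = ops.kappa.shape
    t_out_ms = np.asarray(t_out_ms, dtype=float)
    steps_out = t_out_ms / dt_ms
    idx_out = np.rint(steps_out).astype(int)
    if np.any(np.abs(steps_out - idx_out) > 1e-9) or np.any(idx_out < 0):
        raise ValueError("output times must be non-negative multiples of the step")
    n_steps = int(idx_out.max())

    dt = dt_ms / 1000.0  # dynamics run in seconds
    t_fine = np.arange(n_steps + 1) * dt_ms
    u = stimulus.waveform(t_fine)
    u_half = stimulus.waveform(t_fine + 0.5 * dt_ms)

    out = np.empty((B, t_out_ms.size, N))
    if _HAVE_NUMBA:
        _rk4_batched(
            ops.kappa, ops.W, ops.msp, ops.sp_idx.astype(np.int64),
            ops.u_in, u, u_half, dt, idx_out.astype(np.int64), out,
        )
    else:
        v = np.zeros((B, N))
        i = np.zeros((B, N))
        want = {k: j for j, k in enumerate(idx_out)}
        if 0 in want:
            out[:, want[0]] = v
        for k in range(n_steps):
            k1v, k1i = cmc_flow(v, i, ops, u[k])
            k2v, k2i = cmc_flow(v + 0.5 * dt * k1v, i + 0.5 * dt * k1i, ops, u_half[k])
            k3v, k3i = cmc_flow(v + 0.5 * dt * k2v, i + 0.5 * dt * k2i, ops, u_half[k])
            k4v, k4i = cmc_flow(v + dt * k3v, i + dt * k3i, ops, u[k + 1])
            v = v + dt / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
            i = i + dt / 6.0 * (k1i + 2 * k2i + 2 * k3i + k4i)
            if (k + 1) in want:
                out[:, want[k + 1]] = v
    if not np.all(np.isfinite(out)):
        bad = np.argwhere(~np.isfinite(out))
        b, _, n = bad[0]
        src = space.network.source_names[n // N_POP]
        pop = ("ss", "sp", "ii", "dp")[n % N_POP]
        raise FloatingPointError(
            f"integration diverged (batch {b}, source {src}, population {pop})"
        )
    return out


def integrate_erp(
    space: ParameterSpace,
    theta: np.ndarray,
    cond: int | str,
    stimulus: StimulusInput | None = None,
    t_out_ms: np.ndarray | None = None,
    dt_ms: float = DEFAULT_DT_MS,
    basis_set: TemporalBasisSet | None = None,
) -> SourceResponse:
    """Integrate one condition and return the per-population source response.

    The default output grid covers 0..300 ms at the recording rate.
    """
    stim = stimulus if stimulus is not None else StimulusInput()
    if t_out_ms is None:
        t_out_ms = np.arange(0.0, EPOCH_MS[1] + 1e-9, 1000.0 / SFREQ)
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 1:
        raise ValueError("integrate_erp takes a single parameter vector")
    states = integrate_states(space, theta, cond, stim, t_out_ms, dt_ms, basis_set)[0]
    S = space.network.n_sources
    v = states.T.reshape(S, N_POP, t_out_ms.size)
    return SourceResponse(times_ms=np.asarray(t_out_ms, float), v=v,
                          source_names=space.network.source_names)


def pyramidal_mixture(states: np.ndarray, n_sources: int) -> np.ndarray:
    """Observable per-source signal: sp + 0.2 dp depolarisation.

    states is (..., T, N) flattened over populations; returns (..., T, S).
    """
    shp = states.shape[:-1] + (n_sources, N_POP)
    x = states.reshape(shp)
    return OBS_WEIGHT_SP * x[..., 1] + OBS_WEIGHT_DP * x[..., 3]


def project_to_sensors(source_response: SourceResponse, leadfield) -> SensorErp:
    """Project a source response through the lead field (0..300 ms window).

    The channel signal is the lead-field-weighted sum of the per-source
    pyramidal mixture; linear and homogeneous in source activity.
    """
    gain = leadfield.gain
    if gain.shape[1] != source_response.v.shape[0]:
        raise ValueError("lead field does not match the number of sources")
    mix = OBS_WEIGHT_SP * source_response.v[:, 1, :] + OBS_WEIGHT_DP * source_response.v[:, 3, :]
    data = gain @ mix  # (C, T)
    t = source_response.times_ms
    return SensorErp(
        data=data,
        sfreq=SFREQ,
        window_ms=(float(t[0]), float(t[-1])),
        channels=tuple(leadfield.channels),
    )


def predict_epochs(
    space: ParameterSpace,
    theta: np.ndarray,
    leadfield,
    stimulus: StimulusInput | None = None,
    dt_ms: float = DEFAULT_DT_MS,
    basis_set: TemporalBasisSet | None = None,
    conditions: tuple[int, ...] = (0, 1, 2, 3),
) -> np.ndarray:
    """Batched noiseless epochs for all conditions on the recording grid.

    theta: (P,) or (B, P).  Returns (B, n_cond, C, T_epoch) covering
    -100..300 ms at 500 Hz, zero before stimulus time 0, scaled by the
    exp of the observation-gain parameter.  No baseline correction is
    applied here.
    """
    stim = stimulus if stimulus is not None else StimulusInput()
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    B = theta.shape[0]
    step_ms = 1000.0 / SFREQ
    t_post = np.arange(0.0, EPOCH_MS[1] + 1e-9, step_ms)
    n_pre = int(round(-EPOCH_MS[0] / step_ms))
    C = leadfield.gain.shape[0]
    T = n_pre + t_post.size
    S = space.network.n_sources
    out = np.zeros((B, len(conditions), C, T))
    g = np.exp(theta[:, space.index("gain")])  # (B,)
    for jc, cond in enumerate(conditions):
        states = integrate_states(space, theta, cond, stim, t_post, dt_ms, basis_set)
        mix = pyramidal_mixture(states, S)  # (B, T_post, S)
        sens = np.einsum("cs,bts->bct", leadfield.gain, mix)
        out[:, jc, :, n_pre:] = g[:, None, None] * sens
    return out


def principal_eigenmode(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First spatial singular mode of a channels x time array.

    Returns ``(temporal, weights)`` where ``temporal`` is the first right
    singular vector scaled by its singular value and ``weights`` the unit
    spatial pattern.  The sign is fixed so the spatial weight of largest
    magnitude is positive; among tied singular values numpy's ordering
    (first mode returned) is kept.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 2:
        raise ValueError("need a channels x time array with >= 2 samples")
    if not np.any(data):
        raise ValueError("eigenmode of identically zero data is undefined")
    u, s, vt = np.linalg.svd(data, full_matrices=False)
    w = u[:, 0]
    sign = np.sign(w[np.argmax(np.abs(w))]) or 1.0
    return sign * s[0] * vt[0], sign * w
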