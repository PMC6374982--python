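"""Canonical-microcircuit neural-mass dynamics for a network of sources.

Each source is a cortical column of four populations -- spiny stellate (ss),
superficial pyramidal (sp), inhibitory interneuron (ii) and deep pyramidal
(dp) -- each modelled as a neural mass with second-order synaptic kernel
dynamics.  Writing v for the population depolarisation and i for its auxiliary
current state, with rate constant kappa = kappa0 * exp(tau),

    dv/dt = i
    di/dt = kappa * u_pre - 2 * kappa * i - kappa**2 * v

where u_pre is the weighted sum of presynaptic firing.  Firing is a logistic
sigmoid of depolarisation with its resting output subtracted, so the all-zero
state with zero input is an exact fixed point.

Intrinsic wiring (weights are fixed base values; the g gains scale them
multiplicatively via exp):

    target <- source   weight   gain
    ss <- ss           -8
    ss <- sp           -4
    ss <- ii           -4       exp(g3)   (the ii->ss inhibition)
    sp <- ss           +4       exp(g1)   (excitatory granular drive)
    sp <- sp           -4       exp(m + n.basis), activity-dependent
    sp <- ii           -2       exp(g2)
    ii <- ss           +4
    ii <- sp           +4       exp(g2)
    ii <- ii           -4
    ii <- dp           +2
    dp <- sp           +3
    dp <- ii           -2
    dp <- dp           -2

Extrinsic forward connections project sp firing of the source region onto ss
of the target; backward connections project dp firing onto sp (inhibitory,
net) and ii (excitatory) of the target.  Effective extrinsic log-couplings
are ``a + sum_k b_k * basis_k(condition)``, exponentiated onto fixed base
weights.  The sp recurrent self-connection carries an additional
activity-dependent (cubic in firing) term whose gain is modulated by the M/N
parameters.

All operator builders are **batched**: they accept a (B, P) stack of
parameter vectors and return (B, ...) arrays so many simulations (e.g. the
finite-difference sensitivities of an inversion) integrate in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .conditions import TemporalBasisSet
from .network import NetworkSpec, POPULATIONS, N_POP
from .params import ParameterSpace

#: Prior-mean population time constants, seconds (ss, sp, ii, dp).
KAPPA0_TIME_CONSTANTS = np.array([0.004, 0.008, 0.016, 0.028])
KAPPA0 = 1.0 / KAPPA0_TIME_CONSTANTS  # rate constants, 1/s

#: Overall synaptic gain applied to every connection weight (dimensionless;
#: the base weights below are in units of this scale).
SYNAPTIC_SCALE = 200.0

#: Intrinsic wiring: (target pop, source pop, base weight, gain tag or None).
INTRINSIC_WIRING: tuple[tuple[str, str, float, str | None], ...] = (
    ("ss", "ss", -8.0, None),
    ("ss", "sp", -4.0, None),
    ("ss", "ii", -4.0, "g3"),
    ("sp", "ss", 4.0, "g1"),
    ("sp", "sp", -4.0, "m"),
    ("sp", "ii", -2.0, "g2"),
    ("ii", "ss", 4.0, None),
    ("ii", "sp", 4.0, "g2"),
    ("ii", "ii", -4.0, None),
    ("ii", "dp", 2.0, None),
    ("dp", "sp", 3.0, None),
    ("dp", "ii", -2.0, None),
    ("dp", "dp", -2.0, None),
)

#: Base weights of extrinsic afferents (scaled by exp of effective coupling).
FORWARD_WEIGHT_SS = 32.0
BACKWARD_WEIGHT_SP = -0.25
BACKWARD_WEIGHT_II = 0.5

#: Exogenous input weight onto ss of input sources.
INPUT_WEIGHT = 12.0

#: Logistic firing-rate slope; threshold 0 so firing is odd in v.
SIGMOID_SLOPE = 2.0 / 3.0

#: Coefficient of the cubic activity-dependent term of the sp recurrent.
SELF_MODULATION_ACT = 1.0

_POP_IDX = {p.value: k for k, p in enumerate(POPULATIONS)}


def firing(v: np.ndarray) -> np.ndarray:
    """Baseline-subtracted logistic firing rate; firing(0) == 0."""
    return 1.0 / (1.0 + np.exp(-SIGMOID_SLOPE * v)) - 0.5


def effective_coupling(
    space: ParameterSpace,
    theta: np.ndarray,
    cond: int | str,
    basis_set: TemporalBasisSet | None = None,
) -> dict[str, float]:
    """Condition-specific effective log-couplings.

    Returns a mapping from parameter-like names (``a_fwd:{edge}``,
    ``a_bwd:{edge}``, ``m:{source}``) to the effective log value
    ``base + sum_k weight_k * basis_k(condition)``.  With all B and N weights
    zero the effective values equal the base values exactly.
    """
    bs = basis_set if basis_set is not None else TemporalBasisSet()
    w = bs.values(cond)
    theta = np.asarray(theta, dtype=float)
    net = space.network
    out: dict[str, float] = {}
    for kind, edges in (("fwd", net.forward), ("bwd", net.backward)):
        for e in edges:
            a = theta[space.index(f"a_{kind}:{e.name}")]
            b = np.array(
                [theta[space.index(f"b_{kind}:{e.name}:mono")],
                 theta[space.index(f"b_{kind}:{e.name}:phas")]]
            )
            out[f"a_{kind}:{e.name}"] = float(a + b @ w)
    for s in net.source_names:
        m = theta[space.index(f"m:{s}")]
        n = np.array(
            [theta[space.index(f"n:{s}:mono")], theta[space.index(f"n:{s}:phas")]]
        )
        out[f"m:{s}"] = float(m + n @ w)
    return out


@dataclass
class FlowOperators:
    """Precomputed batched operators for one condition.

    kappa : (B, N) rate constants (N = sources x populations)
    W     : (B, N, N) linear weight matrix applied to firing
    msp   : (B, S) coefficient of the cubic sp self term
    u_in  : (N,) exogenous input weights
    """

    kappa: np.ndarray
    W: np.ndarray
    msp: np.ndarray
    u_in: np.ndarray
    sp_idx: np.ndarray

    @property
    def batch(self) -> int:
        return self.kappa.shape[0]


def condition_operators(
    space: ParameterSpace,
    theta: np.ndarray,
    cond: int | str,
    basis_set: TemporalBasisSet | None = None,
) -> FlowOperators:
    """Assemble batched flow operators for one condition.

    ``theta`` may be a single (P,) vector or a (B, P) stack.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[1] != space.size:
        raise ValueError(f"parameter vectors must have length {space.size}")
    bs = basis_set if basis_set is not None else TemporalBasisSet()
    w = bs.values(cond)  # (2,)
    net = space.network
    S = net.n_sources
    N = S * N_POP
    B = theta.shape[0]

    tau = theta[:, space.group("tau")].reshape(B, S, N_POP)
    kappa = (KAPPA0[None, None, :] * np.exp(tau)).reshape(B, N)

    gvals = theta[:, space.group("g")].reshape(B, S, 3)
    gain = {f"g{k}": np.exp(gvals[:, :, k - 1]) for k in (1, 2, 3)}  # (B, S)
    n_w = theta[:, space.group("n")].reshape(B, S, 2)
    m_eff = theta[:, space.group("m")].reshape(B, S) + n_w @ w
    gain["m"] = np.exp(m_eff)

    W = np.zeros((B, N, N))
    for tgt, src, wgt, tag in INTRINSIC_WIRING:
        ti, si = _POP_IDX[tgt], _POP_IDX[src]
        rows = np.arange(S) * N_POP + ti
        cols = np.arange(S) * N_POP + si
        scale = gain[tag] if tag is not None else 1.0
        W[:, rows, cols] += wgt * scale

    def _edge_log(kind: str, edges) -> np.ndarray:
        a = np.stack([theta[:, space.index(f"a_{kind}:{e.name}")] for e in edges], axis=1)
        b = np.stack(
            [
                np.stack(
                    [theta[:, space.index(f"b_{kind}:{e.name}:mono")],
                     theta[:, space.index(f"b_{kind}:{e.name}:phas")]],
                    axis=1,
                )
                for e in edges
            ],
            axis=1,
        )  # (B, E, 2)
        return a + b @ w  # (B, E)

    fwd_log = _edge_log("fwd", net.forward)
    for j, e in enumerate(net.forward):
        si = net.source_index(e.src) * N_POP + _POP_IDX["sp"]
        ti = net.source_index(e.dst) * N_POP + _POP_IDX["ss"]
        W[:, ti, si] += FORWARD_WEIGHT_SS * np.exp(fwd_log[:, j])
    bwd_log = _edge_log("bwd", net.backward)
    for j, e in enumerate(net.backward):
        si = net.source_index(e.src) * N_POP + _POP_IDX["dp"]
        c = np.exp(bwd_log[:, j])
        W[:, net.source_index(e.dst) * N_POP + _POP_IDX["sp"], si] += BACKWARD_WEIGHT_SP * c
        W[:, net.source_index(e.dst) * N_POP + _POP_IDX["ii"], si] += BACKWARD_WEIGHT_II * c

    W *= SYNAPTIC_SCALE
    msp = -4.0 * SYNAPTIC_SCALE * gain["m"] * SELF_MODULATION_ACT  # (B, S)

    u_in = np.zeros(N)
    for s in net.inputs:
        u_in[net.source_index(s) * N_POP + _POP_IDX["ss"]] = INPUT_WEIGHT * SYNAPTIC_SCALE

    sp_idx = np.arange(S) * N_POP + _POP_IDX["sp"]
    return FlowOperators(kappa=kappa, W=W, msp=msp, u_in=u_in, sp_idx=sp_idx)


def cmc_flow(
    v: np.ndarray, i: np.ndarray, ops: FlowOperators, u_t: float
) -> tuple[np.ndarray, np.ndarray]:
    """Time derivative of the batched state (v, i); u_t is the scalar drive.

    Raises ValueError on a state/operator dimension mismatch.
    """
    if v.shape != i.shape or v.shape[-1] != ops.kappa.shape[-1]:
        raise ValueError("state dimensions do not match flow operators")
    s = firing(v)
    drive = np.einsum("bij,bj->bi", ops.W, s)
    ssp = s[:, ops.sp_idx]
    drive[:, ops.sp_idx] += ops.msp * ssp**3
    drive += ops.u_in[None, :] * u_t
    dv = i
    di = ops.kappa * drive - 2.0 * ops.kappa * i - ops.kappa**2 * v
    return dv, di
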