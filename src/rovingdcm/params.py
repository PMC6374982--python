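"""Flat parameter vector for the microcircuit network, with a name<->index map.

All neuronal parameters are **log-scale deviations**: a value of 0 leaves the
prior-mean constant unchanged, and the effective multiplicative factor is
``exp(value)``.  The flat vector concatenates, in order,

* ``tau:{source}:{pop}`` - population rate-constant deviations (4 per source),
* ``g:{source}:g{1,2,3}`` - intrinsic coupling gains (g3 is ii->ss inhibition),
* ``m:{source}`` - activity-dependent self-modulation of the sp recurrent,
* ``a_fwd:{edge}`` / ``a_bwd:{edge}`` - extrinsic coupling per directed edge,
* ``b_fwd:{edge}:{basis}`` / ``b_bwd:{edge}:{basis}`` - condition modulations,
* ``n:{source}:{basis}`` - condition modulations of the sp self-modulation,
* ``gain`` - log observation gain.

Group slices (``tau``, ``g``, ``g3``, ``m``, ``a``, ``b``, ``n``, ``gain``...)
index the vector for priors, model reduction and second-level analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .conditions import BASIS_NAMES
from .network import NetworkSpec, POPULATIONS

#: Default prior variances per parameter group (log-scale deviations).
DEFAULT_PRIOR_VARIANCES: dict[str, float] = {
    "tau": 1.0 / 64.0,
    "g": 1.0 / 16.0,
    "m": 1.0 / 16.0,
    "a": 1.0 / 16.0,
    "b": 1.0 / 16.0,
    "n": 1.0 / 16.0,
    "gain": 1.0 / 16.0,
}


@dataclass(frozen=True)
class ParameterSpace:
    """Name<->index map over the flattened parameter vector of a network."""

    network: NetworkSpec
    names: tuple[str, ...] = field(init=False)
    _groups: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        net = self.network
        names: list[str] = []
        groups: dict[str, list[int]] = {}

        def add(name: str, *tags: str) -> None:
            idx = len(names)
            names.append(name)
            for t in tags:
                groups.setdefault(t, []).append(idx)

        for s in net.source_names:
            for p in POPULATIONS:
                add(f"tau:{s}:{p.value}", "tau", "intrinsic")
        for s in net.source_names:
            for k in (1, 2, 3):
                tags = ["g", "intrinsic"] + (["g3"] if k == 3 else [])
                add(f"g:{s}:g{k}", *tags)
        for s in net.source_names:
            add(f"m:{s}", "m", "intrinsic")
        for e in net.forward:
            add(f"a_fwd:{e.name}", "a", "a_fwd", "extrinsic")
        for e in net.backward:
            add(f"a_bwd:{e.name}", "a", "a_bwd", "extrinsic")
        for e in net.forward:
            for b in BASIS_NAMES:
                add(f"b_fwd:{e.name}:{b}", "b", "b_fwd", "extrinsic", f"basis_{b}")
        for e in net.backward:
            for b in BASIS_NAMES:
                add(f"b_bwd:{e.name}:{b}", "b", "b_bwd", "extrinsic", f"basis_{b}")
        for s in net.source_names:
            for b in BASIS_NAMES:
                add(f"n:{s}:{b}", "n", "intrinsic", f"basis_{b}")
        add("gain", "gain")

        object.__setattr__(self, "names", tuple(names))
        object.__setattr__(self, "_groups", {k: np.asarray(v) for k, v in groups.items()})

    @property
    def size(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None

    def group(self, tag: str) -> np.ndarray:
        """Indices of a parameter group (copy)."""
        if tag not in self._groups:
            raise KeyError(f"unknown parameter group {tag!r}; have {sorted(self._groups)}")
        return self._groups[tag].copy()

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(self._groups)

    def zeros(self) -> np.ndarray:
        return np.zeros(self.size)

    def vector(self, values: dict[str, float]) -> np.ndarray:
        """Build a parameter vector from a {name: value} mapping (rest zero)."""
        theta = self.zeros()
        for k, v in values.items():
            theta[self.index(k)] = v
        return theta

    def prior_variance_vector(
        self, variances: dict[str, float] | None = None
    ) -> np.ndarray:
        """Per-parameter prior variances built from per-group values."""
        var = dict(DEFAULT_PRIOR_VARIANCES)
        if variances:
            var.update(variances)
        out = np.zeros(self.size)
        for tag in ("tau", "g", "m", "a", "b", "n", "gain"):
            out[self.group(tag)] = var[tag]
        return out


@dataclass
class SourceParameters:
    """Per-source intrinsic log-deviations: tau (4), g (3), m_gain."""

    tau: np.ndarray
    g: np.ndarray
    m_gain: float

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.tau.shape != (4,) or self.g.shape != (3,):
            raise ValueError("tau must have 4 entries and g 3 entries")
        if not (np.all(np.isfinite(self.tau)) and np.all(np.isfinite(self.g)) and np.isfinite(self.m_gain)):
            raise ValueError("source parameters must be finite")


@dataclass
class ExtrinsicCoupling:
    """Extrinsic log-couplings and condition-modulation weights.

    ``a_fwd``/``a_bwd`` map edge name -> log-coupling; ``b_fwd``/``b_bwd`` map
    edge name -> per-basis weights; ``n_mod`` maps source name -> per-basis
    weights on the sp self-modulation.
    """

    a_fwd: dict
    a_bwd: dict
    b_fwd: dict
    b_bwd: dict
    n_mod: dict


def unpack(space: ParameterSpace, theta: np.ndarray):
    """Split a flat vector into per-source and extrinsic structured views."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (space.size,):
        raise ValueError(f"expected vector of length {space.size}, got {theta.shape}")
    net = space.network
    per_source = {}
    for s in net.source_names:
        tau = np.array([theta[space.index(f"tau:{s}:{p.value}")] for p in POPULATIONS])
        g = np.array([theta[space.index(f"g:{s}:g{k}")] for k in (1, 2, 3)])
        per_source[s] = SourceParameters(tau, g, float(theta[space.index(f"m:{s}")]))
    ext = ExtrinsicCoupling(
        a_fwd={e.name: float(theta[space.index(f"a_fwd:{e.name}")]) for e in net.forward},
        a_bwd={e.name: float(theta[space.index(f"a_bwd:{e.name}")]) for e in net.backward},
        b_fwd={
            e.name: np.array([theta[space.index(f"b_fwd:{e.name}:{b}")] for b in BASIS_NAMES])
            for e in net.forward
        },
        b_bwd={
            e.name: np.array([theta[space.index(f"b_bwd:{e.name}:{b}")] for b in BASIS_NAMES])
            for e in net.backward
        },
        n_mod={
            s: np.array([theta[space.index(f"n:{s}:{b}")] for b in BASIS_NAMES])
            for s in net.source_names
        },
    )
    return per_source, ext
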