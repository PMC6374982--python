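"""The six-source auditory hierarchy and its population types.

The network spans bilateral primary auditory cortex (A1), superior temporal
gyrus (STG) and inferior frontal gyrus (IFG), coupled in a two-step hierarchy
A1 -> STG -> IFG in each hemisphere.  Forward connections climb the hierarchy,
backward connections descend it, and the exogenous auditory input drives
bilateral A1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class PopulationKind(str, Enum):
    """The four neuronal populations of a canonical microcircuit."""

    SS = "ss"  # spiny stellate (granular, excitatory)
    SP = "sp"  # superficial pyramidal (supragranular, excitatory)
    II = "ii"  # inhibitory interneuron
    DP = "dp"  # deep pyramidal (infragranular, excitatory)

    @property
    def is_excitatory(self) -> bool:
        return self is not PopulationKind.II


POPULATIONS: tuple[PopulationKind, ...] = (
    PopulationKind.SS,
    PopulationKind.SP,
    PopulationKind.II,
    PopulationKind.DP,
)
N_POP = len(POPULATIONS)


@dataclass(frozen=True)
class Source:
    name: str
    mni: tuple[float, float, float]


@dataclass(frozen=True)
class Edge:
    """A directed extrinsic connection between two sources."""

    src: str
    dst: str

    @property
    def name(self) -> str:
        return f"{self.src}->{self.dst}"


@dataclass(frozen=True)
class NetworkSpec:
    """Sources, forward/backward edge sets and input sources of the network.

    Invariants: the backward edge set is the element-wise reverse of the
    forward set, and every edge endpoint is a declared source.
    """

    sources: tuple[Source, ...]
    forward: tuple[Edge, ...]
    backward: tuple[Edge, ...]
    inputs: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sources]
        if len(set(names)) != len(names):
            raise ValueError("duplicate source names")
        for e in self.forward + self.backward:
            if e.src not in names or e.dst not in names:
                raise ValueError(f"edge {e.name} references undeclared source")
        rev = {(e.dst, e.src) for e in self.forward}
        if {(e.src, e.dst) for e in self.backward} != rev:
            raise ValueError("backward edges must be the reverses of forward edges")
        for s in self.inputs:
            if s not in names:
                raise ValueError(f"input source {s} undeclared")
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    @property
    def source_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.sources)

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    def source_index(self, name: str) -> int:
        return self._index[name]


#: MNI coordinates of the six sources (mm).
DEFAULT_COORDS: dict[str, tuple[float, float, float]] = {
    "lA1": (-42.0, -22.0, 7.0),
    "rA1": (46.0, -14.0, 8.0),
    "lSTG": (-61.0, -32.0, 8.0),
    "rSTG": (59.0, -25.0, 8.0),
    "lIFG": (-46.0, 20.0, 8.0),
    "rIFG": (46.0, 20.0, 8.0),
}

SOURCE_NAMES: tuple[str, ...] = tuple(DEFAULT_COORDS)


def network_to_dict(net: NetworkSpec) -> dict:
    """JSON-ready description of a network (sources, edges, inputs)."""
    return {
        "sources": [{"name": s.name, "mni": list(s.mni)} for s in net.sources],
        "forward": [[e.src, e.dst] for e in net.forward],
        "inputs": list(net.inputs),
    }


def network_from_dict(data: dict) -> NetworkSpec:
    """Build a network from a JSON document; backward edges are implied."""
    fwd = tuple(Edge(s, d) for s, d in data["forward"])
    return NetworkSpec(
        sources=tuple(Source(s["name"], tuple(s["mni"])) for s in data["sources"]),
        forward=fwd,
        backward=tuple(Edge(e.dst, e.src) for e in fwd),
        inputs=tuple(data["inputs"]),
    )


def load_model_specification(path) -> dict:
    """Load a network/prior/basis JSON specification.

    Returns a dict with keys ``network`` (NetworkSpec), ``prior_variances``
    (per-group dict, may be empty) and ``basis`` (TemporalBasisSet).
    """
    import json
    from pathlib import Path

    from .conditions import TemporalBasisSet

    data = json.loads(Path(path).read_text())
    basis_cfg = data.get("basis", {})
    return {
        "network": network_from_dict(data),
        "prior_variances": data.get("prior_variances", {}),
        "basis": TemporalBasisSet(
            lambda_mono=basis_cfg.get("lambda_mono", 8.0),
            lambda_phasic=basis_cfg.get("lambda_phasic", 2.0),
        ),
    }


def build_default_network() -> NetworkSpec:
    """Build the default 6-source A1 -> STG -> IFG bilateral hierarchy.

    Forward edges: lA1->lSTG, rA1->rSTG, lSTG->lIFG, rSTG->rIFG; backward
    edges are their reverses; bilateral A1 receives the stimulus input.
    """
    fwd = (
        Edge("lA1", "lSTG"),
        Edge("rA1", "rSTG"),
        Edge("lSTG", "lIFG"),
        Edge("rSTG", "rIFG"),
    )
    bwd = tuple(Edge(e.dst, e.src) for e in fwd)
    return NetworkSpec(
        sources=tuple(Source(n, c) for n, c in DEFAULT_COORDS.items()),
        forward=fwd,
        backward=bwd,
        inputs=("lA1", "rA1"),
    )
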