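"""First- and second-level model spaces.

First level: repetition effects may modulate forward connections (F),
backward connections (B) and/or intrinsic gain (i), each crossed with the
basis configuration (monophasic only, phasic only, or both), giving
2 x 2 x 2 connection-family patterns x 3 basis configurations = 24 models.

Second level: candidate explanations of the ketamine effect as changes in
combinations of parameter groups, split into exclusively-extrinsic models
(subsets of {A, B}) and exclusively-intrinsic models (subsets of
{tau, g, M, N}).  The default roster (3 extrinsic + 11 intrinsic = 14
models) ships as JSON package data and can be replaced by configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .bmr import reduce_prior
from .params import ParameterSpace
from .vl import GaussianDensity

#: Maps declared second-level group symbols to parameter-space group tags.
GROUP_TAGS = {"A": "a", "B": "b", "tau": "tau", "g": "g", "M": "m", "N": "n"}
EXTRINSIC_GROUPS = ("A", "B")
INTRINSIC_GROUPS = ("tau", "g", "M", "N")


@dataclass(frozen=True)
class ReducedModel:
    """A first-level reduced model: which modulation groups are free."""

    name: str
    free_forward: bool
    free_backward: bool
    free_intrinsic: bool
    basis: str  # "mono" | "phas" | "both"

    def fixed_parameter_names(self, space: ParameterSpace) -> list[str]:
        """Parameters pinned (near-zero prior variance) under this model."""
        fixed: set[str] = set()
        names = space.names
        if not self.free_forward:
            fixed.update(names[i] for i in space.group("b_fwd"))
        if not self.free_backward:
            fixed.update(names[i] for i in space.group("b_bwd"))
        if not self.free_intrinsic:
            fixed.update(names[i] for i in space.group("n"))
        if self.basis != "both":
            unused = "phas" if self.basis == "mono" else "mono"
            fixed.update(names[i] for i in space.group(f"basis_{unused}"))
        return sorted(fixed)

    def reduced_prior(self, space: ParameterSpace, prior: GaussianDensity) -> GaussianDensity:
        """Prior with the excluded modulations switched off (pinned at 0)."""
        fixed = self.fixed_parameter_names(space)
        return reduce_prior(prior, fixed, fixed_mean=0.0) if fixed else prior.copy()


def enumerate_first_level_space() -> list[ReducedModel]:
    """The 24 first-level models (8 F/B/i patterns x 3 basis configurations).

    Names encode the pattern, e.g. "FBi/both" (the full model) or "0/mono"
    (no condition effects, monophasic basis only).
    """
    models = []
    for basis in ("mono", "phas", "both"):
        for f in (True, False):
            for b in (True, False):
                for i in (True, False):
                    pat = ("F" if f else "") + ("B" if b else "") + ("i" if i else "")
                    models.append(
                        ReducedModel(
                            name=f"{pat or '0'}/{basis}",
                            free_forward=f,
                            free_backward=b,
                            free_intrinsic=i,
                            basis=basis,
                        )
                    )
    return models


@dataclass(frozen=True)
class SecondLevelModel:
    """A second-level model: which groups carry a ketamine effect."""

    name: str
    family: str  # "extrinsic" | "intrinsic"
    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        allowed = EXTRINSIC_GROUPS if self.family == "extrinsic" else INTRINSIC_GROUPS
        if self.family not in ("extrinsic", "intrinsic"):
            raise ValueError(f"unknown family {self.family!r}")
        bad = [g for g in self.groups if g not in allowed]
        if bad:
            raise ValueError(f"{self.family} model {self.name} frees foreign groups {bad}")

    def free_tags(self) -> tuple[str, ...]:
        return tuple(GROUP_TAGS[g] for g in self.groups)


def enumerate_second_level_space(path: str | None = None) -> list[SecondLevelModel]:
    """Load the declared second-level space (default: shipped 14-model roster)."""
    if path is None:
        text = resources.files("rovingdcm.data").joinpath("second_level_space.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    spec = json.loads(text)
    models = [
        SecondLevelModel(name=m["name"], family=m["family"], groups=tuple(m["groups"]))
        for m in spec["models"]
    ]
    names = [m.name for m in models]
    if len(set(names)) != len(names):
        raise ValueError("duplicate model names in second-level space")
    return models
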