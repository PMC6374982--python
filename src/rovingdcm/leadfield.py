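"""Synthetic EEG lead field: single-dipole gain in a homogeneous sphere.

The study's anatomical head model is out of scope here; what the group
analysis needs from the forward model is a fixed, source-separating linear
map from the six cortical sources to the 20-channel 10/20 montage.  We place
one equivalent current dipole per source at its MNI coordinate, orient it
(near-)radially, and evaluate the quasi-static potential of a current dipole
in a homogeneous conducting medium at idealised 10/20 electrode positions
(taken from MNE's standard_1020 montage), then re-reference to the channel
average.  This preserves the frontal/temporal topographic separation between
IFG, STG and A1 sources that the hierarchy relies on, without any anatomy.

Dipole orientations follow a fixed per-class sign convention -- near-radial,
outward for the frontal (IFG) sources -- chosen so that, combined with the
microcircuit's pyramidal deflections, the deviant-minus-standard difference
wave expresses the canonical frontocentral negativity at Fz.
Temporal-lobe sources (A1, STG) are given tangential orientations -- their
average-referenced projection onto the frontocentral midline (Fz) is nulled
exactly -- so midline-frontal sensitivity is carried by the frontal (IFG)
sources, mirroring the frontocentral expression of mismatch effects that the
group analysis reads out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import NetworkSpec

#: The 20-channel 10/20 montage (EASYCAP-style: 19 standard sites + Oz).
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

FRONTAL_CHANNELS: frozenset[str] = frozenset(
    {"Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"}
)

_CONDUCTIVITY = 0.33  # S/m, brain/scalp quasi-static
_ORIENT_JITTER = 0.15  # SD of the seeded tangential perturbation


@dataclass(frozen=True)
class LeadField:
    """Channels x sources gain matrix with montage and dipole orientations."""

    gain: np.ndarray
    channels: tuple[str, ...]
    orientations: np.ndarray  # (n_sources, 3), unit vectors

    def __post_init__(self) -> None:
        if self.gain.shape[0] != len(self.channels):
            raise ValueError("gain rows must match channel count")
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("lead field must be finite")
        if np.any(~self.gain.any(axis=1)):
            raise ValueError("lead field has an all-zero channel row")


def electrode_positions(channels: tuple[str, ...]) -> np.ndarray:
    """Idealised electrode positions (metres, head frame) from MNE."""
    import warnings

    import mne

    with warnings.catch_warnings():
        # montage naming is in flux across mne releases
        warnings.simplefilter("ignore", FutureWarning)
        montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    missing = [c for c in channels if c not in pos]
    if missing:
        raise KeyError(f"channels missing from standard_1020: {missing}")
    return np.stack([pos[c] for c in channels])


def make_synthetic_leadfield(
    montage: tuple[str, ...] = DEFAULT_MONTAGE,
    network: NetworkSpec | None = None,
    seed: int = 0,
) -> LeadField:
    """Deterministic-given-seed gain matrix for the network's sources.

    The seed only perturbs the dipole orientations slightly around the inward
    radial direction, emulating inter-individual orientation variability.
    """
    from .network import build_default_network

    if len(montage) < 1:
        raise ValueError("montage must contain at least one channel")
    net = network if network is not None else build_default_network()
    elec = electrode_positions(tuple(montage))  # (C, 3)
    src = np.array([s.mni for s in net.sources]) / 1000.0  # mm -> m

    rng = np.random.default_rng(seed)
    try:
        i_fz = list(montage).index("Fz")
    except ValueError:
        i_fz = None
    orientations = np.empty((net.n_sources, 3))
    gain = np.empty((len(montage), net.n_sources))
    for j, name in enumerate(net.source_names):
        d = elec - src[j][None, :]  # (C, 3)
        r3 = np.linalg.norm(d, axis=1) ** 3
        lead = d / r3[:, None]  # avg-ref lead vectors, (C, 3)
        lead -= lead.mean(axis=0, keepdims=True)
        radial = -src[j] / np.linalg.norm(src[j])  # inward
        if "IFG" in name:
            radial = -radial  # frontal sources: outward (sign convention)
        v = radial + _ORIENT_JITTER * rng.standard_normal(3)
        if i_fz is not None and ("A1" in name or "STG" in name):
            # tangential: null the average-referenced Fz sensitivity exactly
            c = lead[i_fz]
            v = v - (v @ c) / (c @ c) * c
        orientations[j] = v / np.linalg.norm(v)
        gain[:, j] = (lead @ orientations[j]) / (4.0 * np.pi * _CONDUCTIVITY)
    # one global scale (not per source: relative source visibility is the
    # physics) so signals land on a unit-order a.u. scale
    gain /= np.sqrt((gain**2).mean())
    return LeadField(gain=gain, channels=tuple(montage), orientations=orientations)
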