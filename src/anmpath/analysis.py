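"""Pathway statistics: energy profiles, non-native contacts, order parameters.

These operations interrogate a finished chain-of-states pathway: how the
two well energies evolve, which residue pairs transiently approach each
other even though they are distant in both end-states (candidate
cross-linking probes), and how simple geometric order parameters —
centre-of-mass distances and three-segment angles of named residue
ranges — progress along the transition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .anm import ANMModel, ModeOverlapProfile, ModeSet, cumulative_overlap, normal_modes
from .pathway import Pathway
from .structures import Site, StructureError, kabsch

__all__ = [
    "ContactEvent",
    "SegmentSpec",
    "energy_profile",
    "nonnative_contacts",
    "com_distance_profile",
    "angle_profile",
    "mode_overlap_profile",
    "contacts_to_json",
]

#: default "far in both end-states" threshold, Å
DEFAULT_FAR = 10.0
#: default "comes close along the path" threshold, Å
DEFAULT_NEAR = 7.0


@dataclass(frozen=True)
class ContactEvent:
    """A residue pair far apart in both end-states that closes along the path."""

    site_i: Site
    site_j: Site
    dist_state_a: float
    dist_state_b: float
    min_dist: float
    min_image: int  # 1-based image index of the closest approach

    def __str__(self) -> str:
        return (f"{self.site_i}–{self.site_j}: {self.dist_state_a:.1f}/"
                f"{self.dist_state_b:.1f} Å in end-states, "
                f"{self.min_dist:.1f} Å at image {self.min_image}")


@dataclass(frozen=True)
class SegmentSpec:
    """A named residue range whose Cα centroid serves as an order-parameter point."""

    name: str
    chain: str
    start: int
    end: int

    def indices(self, sites: Sequence[Site]) -> np.ndarray:
        idx = np.array([
            i for i, s in enumerate(sites)
            if s.chain == self.chain and self.start <= s.resnum <= self.end
        ])
        if idx.size == 0:
            raise StructureError(
                f"segment {self.name!r} ({self.chain} {self.start}-{self.end}) "
                "matches no resolved residues"
            )
        return idx

    def centroid(self, sites: Sequence[Site], coords: np.ndarray) -> np.ndarray:
        """Unweighted Cα centroid of the segment in one conformer."""
        return coords[self.indices(sites)].mean(axis=0)


def energy_profile(pathway: Pathway) -> pd.DataFrame:
    """Per-image energy and RMSD table (index, E_A, E_B, active E, surface, RMSDs)."""
    return pathway.to_dataframe()


def nonnative_contacts(
    pathway: Pathway,
    far: float = DEFAULT_FAR,
    near: float = DEFAULT_NEAR,
) -> list[ContactEvent]:
    """Residue pairs > ``far`` Å apart in both end-states that come < ``near`` Å.

    Distances are Cα–Cα (the model's only atoms).  The scan is exhaustive
    over all residue pairs and all images; results are sorted by the
    minimum along-path distance.
    """
    if not far > near > 0:
        raise ValueError(f"thresholds must satisfy far > near > 0, got {far}, {near}")
    n = pathway.frames.shape[1]
    iu = np.triu_indices(n, k=1)
    d_a = pdist(pathway.frames[0])
    d_b = pdist(pathway.frames[-1])
    candidate = (d_a > far) & (d_b > far)
    if not np.any(candidate):
        return []
    cand = np.nonzero(candidate)[0]
    mins = np.full(cand.size, np.inf)
    argmins = np.zeros(cand.size, dtype=int)
    for m, frame in enumerate(pathway.frames):
        d = pdist(frame)[cand]
        closer = d < mins
        mins[closer] = d[closer]
        argmins[closer] = m
    events = []
    for c, dmin, m in zip(cand, mins, argmins):
        if dmin < near:
            i, j = int(iu[0][c]), int(iu[1][c])
            events.append(ContactEvent(
                pathway.sites[i], pathway.sites[j],
                float(d_a[c]), float(d_b[c]), float(dmin), int(m) + 1,
            ))
    events.sort(key=lambda e: e.min_dist)
    return events


def contacts_to_json(events: Sequence[ContactEvent], path: str | Path) -> None:
    payload = [
        {
            "residue_i": str(e.site_i), "residue_j": str(e.site_j),
            "dist_state_a": e.dist_state_a, "dist_state_b": e.dist_state_b,
            "min_dist": e.min_dist, "min_image": e.min_image,
        }
        for e in events
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def com_distance_profile(
    pathway: Pathway, seg_a: SegmentSpec, seg_b: SegmentSpec
) -> np.ndarray:
    """Per-image distance between two segment centroids (Å)."""
    ia = seg_a.indices(pathway.sites)
    ib = seg_b.indices(pathway.sites)
    ca = pathway.frames[:, ia].mean(axis=1)
    cb = pathway.frames[:, ib].mean(axis=1)
    return np.linalg.norm(ca - cb, axis=1)


def angle_profile(
    pathway: Pathway,
    seg1: SegmentSpec,
    seg2: SegmentSpec,
    seg3: SegmentSpec,
) -> np.ndarray:
    """Per-image angle (degrees) at the centroid of ``seg2``.

    The angle between the centroid of ``seg1`` and the centroid of ``seg3``
    as seen from the vertex centroid of ``seg2`` — the standard
    three-segment domain-orientation order parameter.
    """
    i1 = seg1.indices(pathway.sites)
    i2 = seg2.indices(pathway.sites)
    i3 = seg3.indices(pathway.sites)
    c1 = pathway.frames[:, i1].mean(axis=1)
    c2 = pathway.frames[:, i2].mean(axis=1)
    c3 = pathway.frames[:, i3].mean(axis=1)
    v1 = c1 - c2
    v3 = c3 - c2
    n1 = np.linalg.norm(v1, axis=1)
    n3 = np.linalg.norm(v3, axis=1)
    if np.any(n1 < 1e-8) or np.any(n3 < 1e-8):
        raise StructureError("coincident segment centroids: angle undefined")
    cosang = np.clip(np.sum(v1 * v3, axis=1) / (n1 * n3), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def mode_overlap_profile(
    pathway: Pathway,
    reference: str = "A",
    images: Sequence[int] | None = None,
    m_max: int | None = None,
    model: ANMModel | None = None,
    modes: ModeSet | None = None,
    k: float = 0.1,
    cutoff: float = 15.0,
) -> list[ModeOverlapProfile]:
    """Cumulative squared cosines of selected images on one end-state's modes.

    For each selected image (1-based indices; default: every image except
    the reference end-state itself), the displacement from the reference
    end structure is superposed onto the reference frame and projected on
    the reference ANM's non-rigid normal modes.  ``CC(m)`` answers how many
    low-frequency modes are needed to capture the structural change up to
    that image.

    The reference ``ModeSet`` (or the ``ANMModel`` to diagonalize) can be
    passed in; otherwise an ANM with the given ``k``/``cutoff`` is built on
    the reference end structure.
    """
    from .anm import build_anm

    ref_frame = pathway.frames[0] if reference == "A" else pathway.frames[-1]
    ref_image = 1 if reference == "A" else pathway.n_images
    if modes is None:
        if model is None:
            model = build_anm(ref_frame, k=k, cutoff=cutoff)
        modes = normal_modes(model)
    if images is None:
        images = [i for i in range(1, pathway.n_images + 1) if i != ref_image]
    m_max = modes.n_modes if m_max is None else min(int(m_max), modes.n_modes)
    profiles = []
    for idx in images:
        frame = pathway.frames[idx - 1]
        # remove any residual rigid-body difference before projecting
        rot, trans = kabsch(frame, ref_frame)
        d = (frame @ rot.T + trans - ref_frame).ravel()
        if d @ d < 1e-16:
            warnings.warn(f"image {idx} coincides with the reference; skipped",
                          stacklevel=2)
            continue
        cc = cumulative_overlap(d, modes, m_max)
        profiles.append(ModeOverlapProfile(f"image {idx}", d, cc))
    return profiles
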