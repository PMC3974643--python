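"""Coarse-grained structures and rigid-body geometry.

A macromolecule is reduced to one site per residue, placed on the Cα atom.
This module reads such site sets from PDB files, matches residues between
two end-states of a conformational transition, superposes them by
least-squares, interpolates between them in Cartesian space and generates
synthetic two-state hinge fixtures for testing.

All coordinates are in Ångström and stored as ``(N, 3)`` float arrays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Site",
    "Structure",
    "PairedSelection",
    "StructureError",
    "read_ca_structure",
    "common_residues",
    "superpose",
    "kabsch",
    "rmsd",
    "linear_interpolate",
    "make_toy_two_state",
    "write_ca_pdb",
    "write_multimodel_pdb",
    "read_multimodel_ca",
]


class StructureError(ValueError):
    """Raised for unusable structural input (missing atoms, degenerate geometry)."""


class Site(NamedTuple):
    """Identity of one coarse-grained site (one residue's Cα)."""

    chain: str
    resnum: int
    icode: str
    resname: str

    @property
    def key(self) -> tuple[str, int, str]:
        """Residue identity used for matching: (chain, number, insertion code)."""
        return (self.chain, self.resnum, self.icode)

    def __str__(self) -> str:  # e.g. "A:GLY12" or "A:GLY12A"
        return f"{self.chain}:{self.resname}{self.resnum}{self.icode.strip()}"


@dataclass(frozen=True)
class Structure:
    """An ordered set of labeled Cα sites with 3D coordinates.

    Parameters
    ----------
    sites : tuple of Site
        Residue identities, in file order.
    coords : (N, 3) ndarray
        Cα positions in Å.
    label : str
        Free-text tag ("open", a PDB id, ...).
    """

    sites: tuple[Site, ...]
    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise StructureError(f"coords must be (N, 3), got {coords.shape}")
        if len(self.sites) != coords.shape[0]:
            raise StructureError(
                f"{len(self.sites)} sites but {coords.shape[0]} coordinate rows"
            )
        if coords.shape[0] < 2:
            raise StructureError("a structure needs at least 2 sites")
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates")
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise StructureError(f"duplicate residue identities: {sorted(dupes)}")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "sites", tuple(self.sites))

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        """Copy of this structure with new coordinates (same sites)."""
        return replace(self, coords=np.asarray(coords, float),
                       label=self.label if label is None else label)

    def subset(self, indices: Sequence[int]) -> "Structure":
        idx = np.asarray(indices, dtype=int)
        return Structure(tuple(self.sites[i] for i in idx), self.coords[idx], self.label)


@dataclass(frozen=True)
class PairedSelection:
    """Order-preserving index map between matched sites of two structures."""

    indices_a: np.ndarray
    indices_b: np.ndarray

    def __post_init__(self) -> None:
        ia = np.asarray(self.indices_a, dtype=int)
        ib = np.asarray(self.indices_b, dtype=int)
        if ia.shape != ib.shape or ia.ndim != 1:
            raise StructureError("paired selections must be equal-length 1D index arrays")
        if len(np.unique(ia)) != ia.size or len(np.unique(ib)) != ib.size:
            raise StructureError("paired selection is not bijective")
        object.__setattr__(self, "indices_a", ia)
        object.__setattr__(self, "indices_b", ib)

    def __len__(self) -> int:
        return self.indices_a.size


# ---------------------------------------------------------------------------
# PDB I/O

def read_ca_structure(
    path: str | Path,
    model: int = 1,
    chains: Sequence[str] | None = None,
    label: str | None = None,
) -> Structure:
    """Read the Cα trace of one model from a PDB file.

    One site per residue; when a Cα has alternate locations the first ALTLOC
    is kept.  Insertion codes are preserved in the residue identity and
    HETATM records are ignored.

    Parameters
    ----------
    path : path to a PDB file with ATOM records.
    model : 1-based model index (NMR/multi-model files).
    chains : optional chain-id whitelist.
    label : structure label; defaults to the file stem.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pdb = parser.get_structure(path.stem, str(path))
    models = list(pdb.get_models())
    if not models:
        raise StructureError(f"{path}: no models found")
    if not 1 <= model <= len(models):
        raise StructureError(f"{path}: model {model} requested, file has {len(models)}")
    mod = models[model - 1]

    sites: list[Site] = []
    xyz: list[np.ndarray] = []
    for chain in mod:
        if chains is not None and chain.id not in chains:
            continue
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip():
                continue
            if "CA" not in res:
                continue
            atom = res["CA"]
            if atom.is_disordered():
                # keep the first ALTLOC in file order
                alt = sorted(atom.disordered_get_id_list())[0]
                atom = atom.disordered_get(alt)
            sites.append(Site(chain.id, int(resseq), icode, res.get_resname().strip()))
            xyz.append(np.asarray(atom.get_coord(), dtype=float))
    if not sites:
        raise StructureError(f"{path}: no Cα atoms after model/chain filtering")
    return Structure(tuple(sites), np.array(xyz), label or path.stem)


_PDB_ATOM = (
    "ATOM  {serial:5d}  CA  {resname:>3s} {chain:1s}{resnum:4d}{icode:1s}   "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}           C\n"
)


def _atom_lines(structure_sites: Sequence[Site], coords: np.ndarray) -> list[str]:
    lines = []
    for i, (site, xyz) in enumerate(zip(structure_sites, coords), start=1):
        lines.append(
            _PDB_ATOM.format(
                serial=i % 100000, resname=site.resname[:3] or "GLY",
                chain=(site.chain or "A")[:1], resnum=site.resnum,
                icode=(site.icode or " ")[:1],
                x=xyz[0], y=xyz[1], z=xyz[2], occ=1.0, b=0.0,
            )
        )
    return lines


def write_ca_pdb(structure: Structure, path: str | Path) -> None:
    """Write a single-model Cα-only PDB file."""
    with open(path, "w") as fh:
        fh.writelines(_atom_lines(structure.sites, structure.coords))
        fh.write("END\n")


def write_multimodel_pdb(
    sites: Sequence[Site], frames: np.ndarray, path: str | Path
) -> None:
    """Write a chain of conformers as a multi-model Cα PDB (one MODEL per image)."""
    frames = np.asarray(frames, float)
    with open(path, "w") as fh:
        for m, coords in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            fh.writelines(_atom_lines(sites, coords))
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_multimodel_ca(path: str | Path) -> tuple[Structure, np.ndarray]:
    """Read a multi-model Cα PDB; returns (first-model Structure, (M, N, 3) frames)."""
    first = read_ca_structure(path, model=1)
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pdb = parser.get_structure("traj", str(path))
    frames = []
    for mod in pdb.get_models():
        xyz = [
            res["CA"].get_coord()
            for chain in mod
            for res in chain
            if not res.id[0].strip() and "CA" in res
        ]
        frames.append(np.asarray(xyz, float))
    frames = np.array(frames)
    if frames.ndim != 3 or frames.shape[1] != first.n_sites:
        raise StructureError(f"{path}: models differ in residue content")
    return first, frames


# ---------------------------------------------------------------------------
# Matching and superposition

def common_residues(a: Structure, b: Structure) -> PairedSelection:
    """Match residues resolved in both structures by (chain, number, icode).

    Order follows structure ``a``.  Residue-name mismatches at a matched
    position (e.g. point mutants) produce a warning, not an error.
    """
    index_b = {site.key: i for i, site in enumerate(b.sites)}
    ia, ib = [], []
    for i, site in enumerate(a.sites):
        j = index_b.get(site.key)
        if j is None:
            continue
        if site.resname != b.sites[j].resname:
            warnings.warn(
                f"residue name mismatch at {site.key}: "
                f"{site.resname} vs {b.sites[j].resname}", stacklevel=2
            )
        ia.append(i)
        ib.append(j)
    if not ia:
        raise StructureError(
            f"no residues in common between {a.label!r} and {b.label!r}"
        )
    return PairedSelection(np.array(ia), np.array(ib))


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between two conformers (no superposition).

    Both arguments are ``(N, 3)`` coordinate arrays of the same length.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise StructureError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) mapping mobile onto reference.

    Returns rotation ``R`` (3x3, det +1) and translation ``t`` such that
    ``mobile @ R.T + t`` minimizes the RMSD to ``reference``.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    H = (mobile - cm).T @ (reference - cr)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    return R, t


def superpose(
    mobile: Structure,
    reference: Structure,
    selection: PairedSelection | None = None,
) -> tuple[Structure, float]:
    """Rigidly superpose ``mobile`` onto ``reference``.

    The optimal rotation/translation is fitted over the paired subset
    (all residues matched by identity when ``selection`` is None) and
    applied to every site of ``mobile``.  The reported RMSD is computed
    over the fitted subset.
    """
    if selection is None:
        selection = common_residues(mobile, reference)
    if len(selection) < 3:
        raise StructureError("superposition needs at least 3 paired sites")
    sub_m = mobile.coords[selection.indices_a]
    sub_r = reference.coords[selection.indices_b]
    # collinear subsets leave a rotation about the line undetermined
    for pts in (sub_m, sub_r):
        s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if s[1] < 1e-8 * max(s[0], 1.0):
            raise StructureError("superposition subset is collinear/degenerate")
    R, t = kabsch(sub_m, sub_r)
    moved = mobile.coords @ R.T + t
    fit_rmsd = rmsd(sub_m @ R.T + t, sub_r)
    return mobile.with_coords(moved), fit_rmsd


# ---------------------------------------------------------------------------
# Interpolation and fixtures

def linear_interpolate(a: np.ndarray, b: np.ndarray, m: int) -> np.ndarray:
    """``m`` conformers spaced uniformly on the Cartesian segment from a to b.

    Conformer ``j`` (1-based) is ``a + j/(m+1) * (b - a)``; the endpoints
    themselves are excluded.  Both end conformers must already share a frame
    (be superposed) for the interpolation to be meaningful.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise StructureError(f"shape mismatch: {a.shape} vs {b.shape}")
    if m < 1:
        raise StructureError(f"interpolant count must be >= 1, got {m}")
    ts = np.arange(1, m + 1) / (m + 1)
    return a[None] + ts[:, None, None] * (b - a)[None]


def make_toy_two_state(
    n_sites: int = 20,
    open_angle: float = 150.0,
    closed_angle: float = 100.0,
    seed: int = 0,
    jitter: float = 0.0,
    spacing: float = 3.8,
    geometry: str = "straight",
) -> tuple[Structure, Structure]:
    """Synthetic two-state hinge fixture: a bead chain that bends at its middle.

    Beads are spaced ``spacing`` Å apart (3.8 Å, the Cα virtual-bond length)
    along two arms meeting at a central hinge site; the two returned
    conformers differ only in the hinge angle (degrees, the interior angle
    between the arm directions).

    ``geometry="straight"`` places each arm on a straight line — the planar
    two-arm construction with a closed-form end-to-end distance, useful for
    geometric oracles but elastically degenerate (straight segments of a
    distance-spring network are transversely floppy).  ``geometry="helix"``
    winds each arm as an α-helix-like coil (2.3 Å radius, 100°/residue,
    consecutive beads still ``spacing`` apart); the resulting network is
    densely connected and well conditioned, the right fixture for normal
    modes and pathway searches.  An optional seeded jitter (Å, identical
    displacements in both conformers) breaks residual symmetry.
    Deterministic for a fixed seed.
    """
    if n_sites < 4:
        raise StructureError("toy chain needs at least 4 sites")
    if geometry not in ("straight", "helix"):
        raise ValueError(f"geometry must be 'straight' or 'helix', got {geometry!r}")
    hinge = (n_sites - 1) // 2
    rng = np.random.default_rng(seed)
    noise = jitter * rng.standard_normal((n_sites, 3)) if jitter > 0 else np.zeros((n_sites, 3))

    def build_straight(angle_deg: float) -> np.ndarray:
        # arm 1 along +x toward the hinge; arm 2 leaves the hinge at the
        # prescribed interior angle, in the xy-plane
        theta = np.deg2rad(angle_deg)
        coords = np.zeros((n_sites, 3))
        for i in range(hinge + 1):
            coords[i] = [(hinge - i) * -spacing, 0.0, 0.0]
        direction = np.array([-np.cos(theta), np.sin(theta), 0.0])
        for i in range(hinge + 1, n_sites):
            coords[i] = coords[hinge] + (i - hinge) * spacing * direction
        return coords + noise

    def build_helix(angle_deg: float) -> np.ndarray:
        radius, omega, rise = 2.3, np.deg2rad(100.0), 1.5
        step = np.hypot(2 * radius * np.sin(omega / 2), rise)
        scale = spacing / step
        radius, rise = radius * scale, rise * scale
        t = np.arange(n_sites)
        coords = np.column_stack([
            radius * np.cos(omega * t), radius * np.sin(omega * t), rise * t
        ])
        # bend the helix axis (z) at the hinge bead by the exterior angle
        ang = np.deg2rad(180.0 - angle_deg)
        ca, sa = np.cos(ang), np.sin(ang)
        rot = np.array([[ca, 0.0, sa], [0.0, 1.0, 0.0], [-sa, 0.0, ca]])
        coords[hinge:] = (coords[hinge:] - coords[hinge]) @ rot.T + coords[hinge]
        return coords + noise

    build = build_straight if geometry == "straight" else build_helix
    sites = tuple(Site("A", i + 1, " ", "GLY") for i in range(n_sites))
    open_s = Structure(sites, build(open_angle), "open")
    closed_s = Structure(sites, build(closed_angle), "closed")
    return open_s, closed_s
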