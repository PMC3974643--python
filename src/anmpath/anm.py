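"""Single-well anisotropic network models (ANM).

An ANM places a node on every Cα of a reference structure and connects
every pair of nodes closer than a cut-off distance ``R_c`` with a Hookean
spring of uniform force constant ``k``:

    E(x) = E0 + (k/2) * sum_{i<j} C_ij (r_ij - r0_ij)^2

where ``C_ij`` is the binary contact matrix of the reference structure and
``r0_ij`` the reference pair distance.  The potential is a function of
internal distances only, hence invariant under rigid-body motion, and its
Hessian at the reference state has an analytic super-element form whose
eigenvectors are the ANM normal modes.

Units: Å for lengths, kcal/mol for energies, kcal/(mol Å²) for ``k``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structures import Structure, StructureError

__all__ = [
    "ANMModel",
    "ModeSet",
    "ModeOverlapProfile",
    "build_anm",
    "anm_energy",
    "anm_force",
    "anm_hessian",
    "normal_modes",
    "cumulative_overlap",
]

#: default uniform spring constant, kcal/(mol Å²)
DEFAULT_K = 0.1
#: default contact cut-off distance, Å
DEFAULT_CUTOFF = 15.0


@dataclass(frozen=True)
class ANMModel:
    """One elastic network: reference geometry, contact topology, parameters.

    Attributes
    ----------
    ref_coords : (N, 3) ndarray
        Reference Cα positions (the experimental structure), Å.
    pairs : (P, 2) int ndarray
        Upper-triangle index pairs (i < j) of the contact matrix.
    ref_dists : (P,) ndarray
        Reference distances of the contact pairs, Å.
    k : float
        Uniform force constant, kcal/(mol Å²).
    cutoff : float
        Contact cut-off R_c, Å.
    e0 : float
        Energy offset of the reference state, kcal/mol.
    """

    ref_coords: np.ndarray
    pairs: np.ndarray
    ref_dists: np.ndarray
    k: float
    cutoff: float
    e0: float = 0.0

    @property
    def n_sites(self) -> int:
        return self.ref_coords.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.pairs.shape[0]

    def contact_matrix(self) -> np.ndarray:
        """Dense binary contact matrix (symmetric, zero diagonal)."""
        n = self.n_sites
        c = np.zeros((n, n), dtype=int)
        c[self.pairs[:, 0], self.pairs[:, 1]] = 1
        return c + c.T


@dataclass(frozen=True)
class ModeSet:
    """Non-rigid normal modes of one ANM, sorted by ascending eigenvalue.

    ``vectors[:, q]`` is the (3N) unit eigenvector of mode ``q`` (0-based;
    mode 1 of the usual 1-based convention).  ``n_discarded`` counts the
    near-zero rigid-body modes removed (6 for a non-degenerate 3D network).
    """

    eigenvalues: np.ndarray
    vectors: np.ndarray
    n_discarded: int

    @property
    def n_modes(self) -> int:
        return self.eigenvalues.size


@dataclass(frozen=True)
class ModeOverlapProfile:
    """Cumulative squared cosines of one displacement on a mode basis."""

    label: str
    displacement: np.ndarray
    cumulative: np.ndarray  # cumulative[m-1] = CC(m)

    def n_modes_for(self, level: float) -> int:
        """Smallest m with CC(m) >= level; -1 if never reached."""
        hit = np.nonzero(self.cumulative >= level)[0]
        return int(hit[0]) + 1 if hit.size else -1


def build_anm(
    reference: Structure | np.ndarray,
    k: float = DEFAULT_K,
    cutoff: float = DEFAULT_CUTOFF,
    e0: float = 0.0,
) -> ANMModel:
    """Build an ANM around a reference structure.

    Every pair of sites within ``cutoff`` of each other in the reference
    becomes a spring.  Sites with no contact at all make the network
    disconnected; they are reported in a warning (an entirely contact-free
    network is an error).
    """
    coords = reference.coords if isinstance(reference, Structure) else np.asarray(reference, float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 2:
        raise StructureError(f"reference coords must be (N>=2, 3), got {coords.shape}")
    if k <= 0 or cutoff <= 0:
        raise ValueError("force constant and cut-off must be positive")
    dists = pdist(coords)
    n = coords.shape[0]
    iu = np.triu_indices(n, k=1)
    mask = dists <= cutoff
    pairs = np.column_stack((iu[0][mask], iu[1][mask]))
    if pairs.shape[0] == 0:
        raise StructureError(f"no contacts at cut-off {cutoff} Å")
    degree = np.bincount(pairs.ravel(), minlength=n)
    lonely = np.nonzero(degree == 0)[0]
    if lonely.size:
        warnings.warn(
            f"network disconnected: sites with no contact at {cutoff} Å: "
            f"{lonely.tolist()}", stacklevel=2
        )
    return ANMModel(coords.copy(), pairs, dists[mask].copy(), float(k), float(cutoff), float(e0))


def _pair_geometry(model: ANMModel, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Displacement vectors and distances of the contact pairs at x."""
    x = np.asarray(x, float).reshape(-1, 3)
    if x.shape[0] != model.n_sites:
        raise StructureError(
            f"conformer has {x.shape[0]} sites, model has {model.n_sites}"
        )
    vec = x[model.pairs[:, 0]] - x[model.pairs[:, 1]]
    dist = np.linalg.norm(vec, axis=1)
    return vec, dist


def anm_energy(model: ANMModel, x: np.ndarray) -> float:
    """ANM potential energy of conformer ``x`` (kcal/mol)."""
    _, dist = _pair_geometry(model, x)
    return model.e0 + 0.5 * model.k * float(np.sum((dist - model.ref_dists) ** 2))


def anm_force(model: ANMModel, x: np.ndarray) -> np.ndarray:
    """Analytic force −∇E at conformer ``x``; shape (N, 3), kcal/(mol Å)."""
    vec, dist = _pair_geometry(model, x)
    if np.any(dist < 1e-10):
        bad = model.pairs[dist < 1e-10]
        raise StructureError(f"coincident contact pair(s) {bad.tolist()}: force undefined")
    # dE/dx_i = k * sum_j C_ij (r_ij - r0_ij) * (x_i - x_j)/r_ij
    coef = model.k * (dist - model.ref_dists) / dist
    pair_force = coef[:, None] * vec
    f = np.zeros((model.n_sites, 3))
    np.add.at(f, model.pairs[:, 0], -pair_force)
    np.add.at(f, model.pairs[:, 1], pair_force)
    return f


def anm_hessian(model: ANMModel) -> np.ndarray:
    """Analytic 3N×3N Hessian of the ANM at its reference structure.

    Off-diagonal super-element for a contact pair (i, j):
    ``H_ij = -k * d d^T / |d|^2`` with ``d = r0_i - r0_j``; diagonal
    super-elements make every block row sum to zero (translation invariance).
    """
    n = model.n_sites
    h = np.zeros((3 * n, 3 * n))
    coords = model.ref_coords
    for (i, j), r0 in zip(model.pairs, model.ref_dists):
        d = coords[i] - coords[j]
        block = -model.k * np.outer(d, d) / (r0 * r0)
        h[3 * i:3 * i + 3, 3 * j:3 * j + 3] += block
        h[3 * j:3 * j + 3, 3 * i:3 * i + 3] += block
        h[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= block
        h[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= block
    return h


def normal_modes(model: ANMModel, zero_tol: float = 1e-8) -> ModeSet:
    """Diagonalize the Hessian and discard the rigid-body null space.

    Eigenpairs with eigenvalue below ``zero_tol`` (relative to the largest
    eigenvalue) are treated as rigid-body modes and removed; more than six
    of them means the network is degenerate (disconnected or collinear) and
    is an error.  Remaining modes are returned in ascending eigenvalue
    order with orthonormal eigenvectors.
    """
    h = anm_hessian(model)
    evals, evecs = np.linalg.eigh(h)
    scale = max(evals[-1], 1e-12)
    near_zero = np.abs(evals) < zero_tol * scale
    n_zero = int(np.count_nonzero(near_zero))
    if n_zero > 6:
        raise StructureError(
            f"degenerate network: {n_zero} near-zero modes (expected <= 6)"
        )
    keep = ~near_zero
    return ModeSet(evals[keep].copy(), evecs[:, keep].copy(), n_zero)


def cumulative_overlap(
    d: np.ndarray, modes: ModeSet, m: int | None = None
) -> np.ndarray:
    """Cumulative squared cosines between a displacement and the lowest modes.

    ``CC(m) = sum_{q<=m} (d · v_q)^2 / |d|^2`` — the fraction of the squared
    displacement captured by the ``m`` lowest-frequency modes.  Returns the
    whole profile ``[CC(1), ..., CC(m)]``; non-decreasing, bounded by 1.
    """
    d = np.asarray(d, float).ravel()
    norm2 = float(d @ d)
    if norm2 <= 0.0:
        raise StructureError("zero displacement: overlap undefined")
    m = modes.n_modes if m is None else int(m)
    if not 1 <= m <= modes.n_modes:
        raise ValueError(f"m must be in 1..{modes.n_modes}, got {m}")
    proj = modes.vectors[:, :m].T @ d
    return np.cumsum(proj ** 2) / norm2
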