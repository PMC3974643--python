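"""Minimum-energy transition pathways on a two-state cusp potential.

Two single-well ANMs, one per experimental end-state, are combined by the
minimum rule

    E(x) = min(E_A(x), E_B(x)),

which has a cusp hypersurface where the two well energies are equal.  The
transition state is defined as the minimum-energy conformer on that
hypersurface.  It is located iteratively: from the current cusp conformer
take one steepest-descent step on each surface (landing on opposite sides
of the cusp) and re-locate the cusp on the segment between the two stepped
conformers.  Two single-surface steepest descents from the converged
transition state, sampled at a fixed RMSD spacing, then yield the
chain-of-states pathway.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .anm import ANMModel, anm_energy, anm_force
from .structures import (
    Site,
    Structure,
    StructureError,
    linear_interpolate,
    rmsd,
    write_multimodel_pdb,
)

__all__ = [
    "TwoStatePotential",
    "SearchSettings",
    "Pathway",
    "ConvergenceError",
    "two_state_energy",
    "locate_cusp",
    "find_transition_state",
    "descend",
    "build_pathway",
]

SURFACE_A = "A"
SURFACE_B = "B"
CUSP = "cusp"


class ConvergenceError(RuntimeError):
    """Raised when the transition-state search or a descent fails to converge."""


@dataclass(frozen=True)
class TwoStatePotential:
    """Pair of ANMs over the same site set, mixed by the cusp min-rule."""

    model_a: ANMModel
    model_b: ANMModel

    def __post_init__(self) -> None:
        if self.model_a.n_sites != self.model_b.n_sites:
            raise StructureError(
                f"end-state models differ in size: "
                f"{self.model_a.n_sites} vs {self.model_b.n_sites}"
            )

    @property
    def n_sites(self) -> int:
        return self.model_a.n_sites

    def energies(self, x: np.ndarray) -> tuple[float, float]:
        """(E_A, E_B) of a conformer."""
        return anm_energy(self.model_a, x), anm_energy(self.model_b, x)

    def model(self, surface: str) -> ANMModel:
        if surface == SURFACE_A:
            return self.model_a
        if surface == SURFACE_B:
            return self.model_b
        raise ValueError(f"unknown surface {surface!r}")


def two_state_energy(pot: TwoStatePotential, x: np.ndarray,
                     tie_tol: float = 0.0) -> tuple[float, str]:
    """Min-rule energy of a conformer and the active surface label.

    Conformers with ``|E_A − E_B| <= tie_tol`` (including exact ties) are
    labeled ``"cusp"``.
    """
    ea, eb = pot.energies(x)
    if abs(ea - eb) <= tie_tol:
        return ea, CUSP
    return (ea, SURFACE_A) if ea < eb else (eb, SURFACE_B)


@dataclass
class SearchSettings:
    """Tunable parameters of the pathway search.

    Attributes
    ----------
    m_interp : int
        Interpolant count for the initial cusp scan (the spacing sets the
        resolution of the energy-equality bracket).
    eps_cusp : float
        Tolerance on |E_A − E_B| for a conformer to count as on-cusp
        (kcal/mol); recommended 1e-4..1e-5.
    eps_converge : float
        Stop the transition-state iteration when successive cusp energies
        differ by less than this (kcal/mol); recommended 1e-4..1e-5.
    step_a, step_b : float
        Steepest-descent step sizes (per unit force) used in the
        transition-state search on surfaces A and B.  Scale inversely with
        the force constant; 0.8–0.4 is appropriate for k = 0.1.
    descent_step : float
        Step size of the image-collecting descents.
    spacing : float
        Target Cα RMSD between consecutive pathway images, Å.
    max_iterations : int
        Cap on transition-state iterations.
    max_descent_steps : int
        Cap on steps of each image-collecting descent.
    energy_floor : float
        Descent stops when the surface energy is within this of E0 (kcal/mol).
    grad_floor : float
        Descent stops when the RMS force drops below this (kcal/(mol Å)).
    adapt_steps : bool
        Halve step sizes automatically when a step would raise the energy
        (the trial-run protocol); when False such a step is a hard error.
    """

    m_interp: int = 100
    eps_cusp: float = 1e-5
    eps_converge: float = 1e-5
    step_a: float = 0.8
    step_b: float = 0.8
    descent_step: float = 0.8
    spacing: float = 0.1
    max_iterations: int = 5000
    max_descent_steps: int = 500_000
    energy_floor: float = 1e-6
    grad_floor: float = 1e-8
    adapt_steps: bool = True

    def __post_init__(self) -> None:
        for name in ("eps_cusp", "eps_converge", "step_a", "step_b",
                     "descent_step", "spacing"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.m_interp < 1:
            raise ValueError("m_interp must be >= 1")


@dataclass
class Pathway:
    """An ordered chain of conformers bridging two end structures.

    ``frames[0]`` and ``frames[-1]`` are the input end structures;
    ``ts_index`` is the 1-based index of the transition-state image.
    """

    sites: tuple[Site, ...]
    frames: np.ndarray            # (n_images, N, 3)
    energies_a: np.ndarray        # E_A per image
    energies_b: np.ndarray        # E_B per image
    surfaces: tuple[str, ...]     # active surface label per image
    ts_index: int                 # 1-based
    spacing: float
    label_a: str = "A"
    label_b: str = "B"

    @property
    def n_images(self) -> int:
        return self.frames.shape[0]

    @property
    def active_energy(self) -> np.ndarray:
        """Min-rule energy per image."""
        return np.minimum(self.energies_a, self.energies_b)

    @property
    def ts_coords(self) -> np.ndarray:
        return self.frames[self.ts_index - 1]

    @property
    def barrier_from_a(self) -> float:
        """Transition-state energy above end-state A (kcal/mol)."""
        return float(self.active_energy[self.ts_index - 1] - self.active_energy[0])

    def rmsd_from(self, which: str) -> np.ndarray:
        """Per-image RMSD from end structure 'A' or 'B' (shared frame)."""
        ref = self.frames[0] if which == "A" else self.frames[-1]
        return np.array([rmsd(f, ref) for f in self.frames])

    def reversed(self) -> "Pathway":
        """The same chain traversed B→A."""
        n = self.n_images
        flip = {SURFACE_A: SURFACE_B, SURFACE_B: SURFACE_A, CUSP: CUSP}
        return Pathway(
            self.sites, self.frames[::-1].copy(),
            self.energies_b[::-1].copy(), self.energies_a[::-1].copy(),
            tuple(flip[s] for s in self.surfaces[::-1]),
            n - self.ts_index + 1, self.spacing, self.label_b, self.label_a,
        )

    # -- output -------------------------------------------------------------

    def to_dataframe(self):
        """Energy/RMSD profile as a pandas DataFrame (one row per image)."""
        import pandas as pd

        return pd.DataFrame({
            "image": np.arange(1, self.n_images + 1),
            "E_A": self.energies_a,
            "E_B": self.energies_b,
            "E_active": self.active_energy,
            "surface": list(self.surfaces),
            "rmsd_from_A": self.rmsd_from("A"),
            "rmsd_from_B": self.rmsd_from("B"),
        })

    def write_pdb(self, path: str | Path) -> None:
        write_multimodel_pdb(self.sites, self.frames, path)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_report(self, path: str | Path, settings: SearchSettings | None = None,
                     extra: dict | None = None) -> None:
        report = {
            "n_images": self.n_images,
            "ts_index": self.ts_index,
            "spacing": self.spacing,
            "barrier_from_A": self.barrier_from_a,
            "end_states": [self.label_a, self.label_b],
        }
        if settings is not None:
            report["settings"] = asdict(settings)
        if extra:
            report.update(extra)
        Path(path).write_text(json.dumps(report, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Cusp localization

def _gap(pot: TwoStatePotential, x: np.ndarray) -> float:
    ea, eb = pot.energies(x)
    return ea - eb


def locate_cusp(
    pot: TwoStatePotential,
    x_lo: np.ndarray,
    x_hi: np.ndarray,
    eps: float = 1e-5,
    m_scan: int = 100,
    max_bisect: int = 200,
) -> np.ndarray:
    """Find a conformer with equal well energies on the segment x_lo → x_hi.

    The energy gap ``E_A − E_B`` must change sign between the endpoints.
    The segment is scanned at ``m_scan`` interior interpolants to bracket
    the sign change, then bisected until ``|E_A − E_B| <= eps``.
    """
    x_lo = np.asarray(x_lo, float)
    x_hi = np.asarray(x_hi, float)
    g_lo, g_hi = _gap(pot, x_lo), _gap(pot, x_hi)
    if abs(g_lo) <= eps:
        return x_lo.copy()
    if abs(g_hi) <= eps:
        return x_hi.copy()
    if np.sign(g_lo) == np.sign(g_hi):
        raise ConvergenceError(
            "endpoints on same side of cusp: no energy-equality crossing on segment"
        )

    def point(t: float) -> np.ndarray:
        return x_lo + t * (x_hi - x_lo)

    # coarse scan to bracket the first crossing
    t_lo, t_hi = 0.0, 1.0
    prev_t, prev_g = 0.0, g_lo
    for j in range(1, m_scan + 2):
        t = j / (m_scan + 1)
        g = _gap(pot, point(t))
        if abs(g) <= eps:
            return point(t)
        if np.sign(g) != np.sign(prev_g):
            t_lo, g_lo, t_hi, g_hi = prev_t, prev_g, t, g
            break
        prev_t, prev_g = t, g

    for _ in range(max_bisect):
        t_mid = 0.5 * (t_lo + t_hi)
        g_mid = _gap(pot, point(t_mid))
        if abs(g_mid) <= eps:
            return point(t_mid)
        if np.sign(g_mid) == np.sign(g_lo):
            t_lo, g_lo = t_mid, g_mid
        else:
            t_hi, g_hi = t_mid, g_mid
    raise ConvergenceError(
        f"cusp bisection did not reach |E_A − E_B| <= {eps} in {max_bisect} steps"
    )


# ---------------------------------------------------------------------------
# Transition-state search

def find_transition_state(
    pot: TwoStatePotential,
    a: Structure | np.ndarray,
    b: Structure | np.ndarray,
    settings: SearchSettings | None = None,
) -> tuple[np.ndarray, list[float]]:
    """Minimum-energy conformer on the cusp hypersurface.

    Starting from the cusp crossing of the straight-line interpolation
    between the (pre-aligned) end structures, iterate: one steepest-descent
    step on each surface (``x + s·F``), then re-locate the cusp on the
    segment between the two stepped conformers.  Converged when successive
    cusp energies agree within ``eps_converge``.

    Returns the transition-state coordinates and the cusp-energy trace
    (one entry per iteration, non-increasing).
    """
    settings = settings or SearchSettings()
    xa0 = a.coords if isinstance(a, Structure) else np.asarray(a, float)
    xb0 = b.coords if isinstance(b, Structure) else np.asarray(b, float)
    if rmsd(xa0, xb0) < 1e-8:
        raise StructureError(
            "end structures are identical: the whole space is on the cusp"
        )
    x = locate_cusp(pot, xa0, xb0, settings.eps_cusp, settings.m_interp)
    s_a, s_b = settings.step_a, settings.step_b
    trace = [two_state_energy(pot, x)[0]]
    halvings = 0
    for _ in range(settings.max_iterations):
        x_a = x + s_a * anm_force(pot.model_a, x)
        x_b = x + s_b * anm_force(pot.model_b, x)
        try:
            x_new = locate_cusp(pot, x_a, x_b, settings.eps_cusp, settings.m_interp)
        except ConvergenceError:
            # overshoot: both stepped conformers crossed to one side
            if not settings.adapt_steps or halvings >= 30:
                raise
            s_a, s_b = 0.5 * s_a, 0.5 * s_b
            halvings += 1
            continue
        e_new = two_state_energy(pot, x_new)[0]
        if e_new > trace[-1] + settings.eps_cusp:
            if not settings.adapt_steps:
                raise ConvergenceError(
                    f"transition-state energy increased ({trace[-1]:.6g} → "
                    f"{e_new:.6g}); rerun with smaller step sizes s_A/s_B"
                )
            if halvings >= 30:
                raise ConvergenceError(
                    "transition-state energy still increasing after 30 step halvings"
                )
            s_a, s_b = 0.5 * s_a, 0.5 * s_b
            halvings += 1
            continue
        converged = abs(trace[-1] - e_new) < settings.eps_converge
        x = x_new
        trace.append(e_new)
        if converged:
            return x, trace
    raise ConvergenceError(
        f"transition-state search did not converge in {settings.max_iterations} "
        "iterations; consider larger eps_converge or different step sizes"
    )


# ---------------------------------------------------------------------------
# Image-collecting descent

def descend(
    pot: TwoStatePotential,
    surface: str,
    start: np.ndarray,
    settings: SearchSettings | None = None,
) -> list[np.ndarray]:
    """Steepest descent on one well, emitting RMSD-spaced images.

    From ``start`` (normally the converged transition state) step
    ``x + s·F`` on the chosen single-well surface; every time the conformer
    has moved at least ``spacing`` (RMSD) from the last emitted image, emit
    a new one.  The per-step displacement is capped at a fraction of the image
    spacing so the emitted chain stays evenly spaced, and within that cap
    the step size adapts: it grows gently while the energy keeps falling
    and is halved (at most 20 times per step, then fatal) whenever a step
    would raise the energy.  Stops when the energy reaches
    ``E0 + energy_floor``, the RMS force drops below ``grad_floor``, or the
    conformer is within half an image spacing of the surface's reference
    structure.

    The well potential depends on internal distances only, so each accepted
    conformer is rigid-body aligned onto the surface's reference structure
    (a pure gauge choice that leaves every energy unchanged).  Without it a
    steepest-descent trajectory accumulates a small net rotation and ends
    at a rigidly rotated copy of the end structure instead of the end
    structure itself.
    """
    from .structures import kabsch

    settings = settings or SearchSettings()
    model = pot.model(surface)
    x = np.asarray(start, float).copy()
    rot, trans = kabsch(x, model.ref_coords)
    x = x @ rot.T + trans
    images: list[np.ndarray] = []
    last_emitted = x.copy()
    s = settings.descent_step
    cap = 0.15 * settings.spacing  # per-step RMS displacement, Å
    e = anm_energy(model, x)
    for _ in range(settings.max_descent_steps):
        f = anm_force(model, x)
        grad_rms = float(np.sqrt(np.mean(np.sum(f ** 2, axis=1))))
        near_ref = rmsd(x, model.ref_coords) < 0.5 * settings.spacing
        if e - model.e0 <= settings.energy_floor or grad_rms < settings.grad_floor or near_ref:
            return images
        s_eff = min(s, cap / grad_rms)
        for halvings in range(21):
            x_try = x + s_eff * f
            rot, trans = kabsch(x_try, model.ref_coords)
            x_try = x_try @ rot.T + trans
            e_try = anm_energy(model, x_try)
            if e_try < e:
                break
            s_eff *= 0.5
        else:
            raise ConvergenceError(
                f"descent on surface {surface} cannot lower the energy "
                "after 20 step halvings"
            )
        s = s_eff * (1.2 if halvings == 0 else 1.0)
        x, e = x_try, e_try
        if rmsd(x, last_emitted) >= settings.spacing:
            images.append(x.copy())
            last_emitted = x.copy()
    raise ConvergenceError(
        f"descent on surface {surface} exceeded {settings.max_descent_steps} steps"
    )


# ---------------------------------------------------------------------------
# Pathway assembly

def build_pathway(
    pot: TwoStatePotential,
    a: Structure,
    b: Structure,
    settings: SearchSettings | None = None,
) -> Pathway:
    """Full pathway: end A, ascending images, transition state, descending images, end B.

    The end structures must already be matched site-for-site and superposed
    (the potential and all RMSD bookkeeping share that one frame).  Image
    indices are 1-based; the transition-state index is recorded.
    """
    settings = settings or SearchSettings()
    ts, trace = find_transition_state(pot, a, b, settings)
    imgs_a = descend(pot, SURFACE_A, ts, settings)
    imgs_b = descend(pot, SURFACE_B, ts, settings)
    frames = [a.coords] + [im for im in reversed(imgs_a)] + [ts] \
        + imgs_b + [b.coords]
    frames = np.array(frames)
    ts_index = 1 + len(imgs_a) + 1  # 1-based: end A + reversed A-side images + TS
    ea = np.array([anm_energy(pot.model_a, f) for f in frames])
    eb = np.array([anm_energy(pot.model_b, f) for f in frames])
    surfaces = []
    for i in range(frames.shape[0]):
        if i == ts_index - 1:
            surfaces.append(CUSP)
        else:
            surfaces.append(SURFACE_A if i < ts_index - 1 else SURFACE_B)
    return Pathway(
        a.sites, frames, ea, eb, tuple(surfaces), ts_index,
        settings.spacing, a.label or "A", b.label or "B",
    )
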