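"""Model/Results interface to the two-state pathway method.

``TransitionPathModel`` is built from the two experimentally determined
end-state structures of a conformational transition.  Construction
performs the data preparation — residue matching, optional
subset-restricted superposition, elastic-network setup — and ``fit()``
runs the transition-state search and the two image-collecting descents,
returning a ``TransitionPathResults`` that carries the pathway, its
energetics and the analysis methods.

Example
-------
>>> from anmpath import TransitionPathModel, make_toy_two_state
>>> open_s, closed_s = make_toy_two_state(n_sites=20)
>>> res = TransitionPathModel(open_s, closed_s, spacing=0.25).fit()
>>> res.n_images, res.ts_index          # doctest: +SKIP
(42, 23)
>>> print(res.summary())                # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .anm import build_anm, DEFAULT_K, DEFAULT_CUTOFF
from .analysis import (
    ContactEvent,
    SegmentSpec,
    mode_overlap_profile,
    nonnative_contacts,
)
from .pathway import (
    Pathway,
    SearchSettings,
    TwoStatePotential,
    build_pathway,
)
from .refine import StringState, string_refine
from .structures import (
    PairedSelection,
    Structure,
    common_residues,
    read_ca_structure,
    superpose,
)

__all__ = ["TransitionPathModel", "TransitionPathResults"]


class TransitionPathModel:
    """Two-state elastic-network model of a conformational transition.

    Parameters
    ----------
    state_a, state_b : Structure
        The two end-state Cα structures.  Residues are matched by
        (chain, number, insertion code); only residues resolved in both
        are retained.
    k : float
        Uniform ANM spring constant, kcal/(mol Å²).
    cutoff : float
        Contact cut-off R_c, Å.
    e0_a, e0_b : float
        Energy offsets of the end-states, kcal/mol (their difference is
        the model's end-state energy gap).
    align_subset : sequence of (chain, start, end), optional
        Residue ranges (e.g. a rigid scaffold) over which state B is
        superposed onto state A; default: all matched residues.
    spacing : float
        Target inter-image Cα RMSD of the fitted pathway, Å.
    settings : SearchSettings, optional
        Full search-parameter control; ``spacing`` overrides its field.
    """

    def __init__(
        self,
        state_a: Structure,
        state_b: Structure,
        k: float = DEFAULT_K,
        cutoff: float = DEFAULT_CUTOFF,
        e0_a: float = 0.0,
        e0_b: float = 0.0,
        align_subset: Sequence[tuple[str, int, int]] | None = None,
        spacing: float = 0.1,
        settings: SearchSettings | None = None,
    ) -> None:
        pairs = common_residues(state_a, state_b)
        self.state_a = state_a.subset(pairs.indices_a)
        state_b_matched = state_b.subset(pairs.indices_b)

        if align_subset:
            keep = [
                i for i, s in enumerate(self.state_a.sites)
                if any(c == s.chain and lo <= s.resnum <= hi
                       for c, lo, hi in align_subset)
            ]
            sel = PairedSelection(np.array(keep), np.array(keep))
        else:
            sel = PairedSelection(
                np.arange(self.state_a.n_sites), np.arange(self.state_a.n_sites)
            )
        self.state_b, self.alignment_rmsd = superpose(
            state_b_matched, self.state_a, sel
        )
        self.k = float(k)
        self.cutoff = float(cutoff)
        self.settings = replace(settings, spacing=spacing) if settings \
            else SearchSettings(spacing=spacing)
        self.potential = TwoStatePotential(
            build_anm(self.state_a, k=k, cutoff=cutoff, e0=e0_a),
            build_anm(self.state_b, k=k, cutoff=cutoff, e0=e0_b),
        )

    @classmethod
    def from_pdb(
        cls,
        path_a: str | Path,
        path_b: str | Path,
        model: int = 1,
        chains: Sequence[str] | None = None,
        **kwargs,
    ) -> "TransitionPathModel":
        """Build the model straight from two PDB files (Cα atoms)."""
        a = read_ca_structure(path_a, model=model, chains=chains)
        b = read_ca_structure(path_b, model=model, chains=chains)
        return cls(a, b, **kwargs)

    @property
    def n_sites(self) -> int:
        return self.state_a.n_sites

    def fit(self, **settings_overrides) -> "TransitionPathResults":
        """Run the transition-state search and assemble the pathway.

        Keyword arguments override individual ``SearchSettings`` fields
        for this fit (e.g. ``step_a=0.4``, ``eps_converge=1e-4``).
        """
        settings = replace(self.settings, **settings_overrides) \
            if settings_overrides else self.settings
        pathway = build_pathway(self.potential, self.state_a, self.state_b, settings)
        return TransitionPathResults(self, pathway, settings)


@dataclass
class TransitionPathResults:
    """Fitted transition pathway with its energetics and diagnostics."""

    model: TransitionPathModel
    pathway: Pathway
    settings: SearchSettings

    # -- headline quantities -------------------------------------------------

    @property
    def n_images(self) -> int:
        return self.pathway.n_images

    @property
    def ts_index(self) -> int:
        """1-based index of the transition-state image."""
        return self.pathway.ts_index

    @property
    def barrier(self) -> float:
        """Transition-state energy above end-state A, kcal/mol."""
        return self.pathway.barrier_from_a

    @property
    def energies(self):
        """Per-image energy/RMSD profile (DataFrame)."""
        return self.pathway.to_dataframe()

    # -- downstream analyses -------------------------------------------------

    def refine(self, beta: float, step: float = 0.4,
               max_iterations: int = 2000, tol: float = 1e-4) -> StringState:
        """Zero-temperature string refinement on the beta-smoothed surface."""
        return string_refine(self.model.potential, self.pathway, beta,
                             step=step, max_iterations=max_iterations, tol=tol)

    def contacts(self, far: float = 10.0, near: float = 7.0) -> list[ContactEvent]:
        """Non-native contacts formed transiently along the pathway."""
        return nonnative_contacts(self.pathway, far=far, near=near)

    def mode_overlap(self, reference: str = "A",
                     images: Sequence[int] | None = None,
                     m_max: int | None = None):
        """Cumulative squared cosines of pathway images on end-state modes."""
        ref_model = self.model.potential.model("A" if reference == "A" else "B")
        return mode_overlap_profile(
            self.pathway, reference=reference, images=images,
            m_max=m_max, model=ref_model,
        )

    def com_distance(self, seg_a: SegmentSpec, seg_b: SegmentSpec) -> np.ndarray:
        from .analysis import com_distance_profile

        return com_distance_profile(self.pathway, seg_a, seg_b)

    def angle(self, seg1: SegmentSpec, seg2: SegmentSpec,
              seg3: SegmentSpec) -> np.ndarray:
        from .analysis import angle_profile

        return angle_profile(self.pathway, seg1, seg2, seg3)

    # -- output ---------------------------------------------------------------

    def save(self, outdir: str | Path, prefix: str = "pathway") -> dict[str, Path]:
        """Write the pathway PDB, the energy TSV and a JSON run report."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "pdb": outdir / f"{prefix}.pdb",
            "tsv": outdir / f"{prefix}_energies.tsv",
            "report": outdir / f"{prefix}_report.json",
        }
        self.pathway.write_pdb(paths["pdb"])
        self.pathway.write_tsv(paths["tsv"])
        self.pathway.write_report(
            paths["report"], self.settings,
            extra={
                "n_sites": self.model.n_sites,
                "k": self.model.k,
                "cutoff": self.model.cutoff,
                "alignment_rmsd": self.model.alignment_rmsd,
            },
        )
        return paths

    def summary(self) -> str:
        """Human-readable run summary."""
        p = self.pathway
        rows = [
            ("End-state A", p.label_a),
            ("End-state B", p.label_b),
            ("Matched Cα sites", f"{self.model.n_sites}"),
            ("Force constant k", f"{self.model.k:g} kcal/(mol Å²)"),
            ("Contact cut-off R_c", f"{self.model.cutoff:g} Å"),
            ("Alignment RMSD (B→A)", f"{self.model.alignment_rmsd:.3f} Å"),
            ("Images", f"{p.n_images}"),
            ("Image spacing (target)", f"{p.spacing:g} Å"),
            ("Transition-state image", f"{p.ts_index}"),
            ("Barrier from A", f"{self.barrier:.4f} kcal/mol"),
            ("E_A − E_B at TS", f"{p.energies_a[p.ts_index-1] - p.energies_b[p.ts_index-1]:.2e} kcal/mol"),
            ("End-state RMSD (A↔B)", f"{p.rmsd_from('A')[-1]:.3f} Å"),
        ]
        width = max(len(k) for k, _ in rows)
        lines = ["Two-state network transition pathway", "=" * 42]
        lines += [f"{k:<{width}} : {v}" for k, v in rows]
        return "\n".join(lines)

    def plot_energy(self, ax=None):
        """Energy along the pathway (active surface, both wells, TS marker)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.energies
        ax.plot(df["image"], df["E_A"], label="$E_A$", lw=1)
        ax.plot(df["image"], df["E_B"], label="$E_B$", lw=1)
        ax.plot(df["image"], df["E_active"], "k.", ms=3, label="active")
        ax.axvline(self.ts_index, color="r", ls="--", lw=1, label="TS")
        ax.set_xlabel("image")
        ax.set_ylabel("energy (kcal/mol)")
        ax.legend()
        return ax
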