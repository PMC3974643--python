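# Methods

## Model

A protein (or any macromolecule with a resolved backbone) is reduced to
one interaction site per residue at the Cα position. One anisotropic
network model (ANM) is built around each of the two experimental
end-state structures: all site pairs within the cut-off R_c in the
reference are connected by springs of uniform force constant k, giving
the single-well energy

E(x) = E0 + (k/2) Σ_{i<j} C_ij (r_ij(x) − r_ij(ref))².

The two wells are combined by the minimum rule E = min(E_A, E_B). The
resulting surface is continuous but non-differentiable on the cusp
hypersurface {x : E_A(x) = E_B(x)}; both wells are convex, so the
minimum of the two-state energy restricted to the cusp is well defined
and is taken as the transition state. The pathway is the concatenation of
the two steepest-descent trajectories from the transition state into the
wells, discretized as conformers ("images") spaced by a fixed Cα RMSD.
Energy offsets E0 shift the wells rigidly and create an end-state energy
difference E0_B − E0_A when desired; they default to zero.

Assumptions inherited from the elastic-network picture: native contact
topology dominates large-scale motion; the harmonic wells are meaningful
far from the references only as an interpolating construct; there are no
side chains, no solvent and no membrane. The uniform k only scales
energies and forces — the geometry of the pathway is k-independent once
step sizes are scaled inversely with k.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| k | spring constant | 0.1 kcal/(mol Å²) | scales energies only |
| R_c | contact cut-off | 15 Å | usual ANM range 10–20 Å |
| E0_A, E0_B | well offsets | 0 | set from experiment if known |
| M | interpolants in the cusp scan | 100 | sets bracket resolution |
| ε₁ | cusp energy-equality tolerance | 10⁻⁵ kcal/mol | recommended 10⁻⁴–10⁻⁵ |
| ε₂ | TS convergence tolerance | 10⁻⁵ kcal/mol | recommended 10⁻⁴–10⁻⁵ |
| s_A, s_B | TS-search descent steps | 0.8 | 0.8–0.4 appropriate at k = 0.1 |
| ΔRMSD | image spacing | 0.1 Å | sets path resolution |
| β | smoothing parameter | user-set, (kcal/mol)⁻¹ | min rule recovered as β → ∞ |

## Algorithms and numerical choices

**Cusp localization.** Given two conformers with opposite signs of
E_A − E_B, the segment between them is scanned at M interior interpolants
to bracket the sign change, then bisected until |E_A − E_B| ≤ ε₁. The
located conformer can sit up to ε₁ below exact equality, so reported
transition-state energies carry an O(ε₁) uncertainty.

**Transition-state iteration.** One force-proportional step x + s·F per
surface, then cusp re-localization between the two stepped conformers;
convergence when successive cusp energies differ by less than ε₂. Steps
that raise the cusp energy (or push both stepped conformers to one side
of the cusp) trigger automatic halving of s_A/s_B, mirroring the
trial-run protocol of starting large and decreasing until the energy
trace is monotone; `adapt_steps=False` turns the halving into a hard
error for users who want explicit control. The energy trace is
non-increasing by construction.

**Image-collecting descent.** Fixed-direction steepest descent x + s·F
on one well, emitting an image whenever the conformer has moved ΔRMSD
from the last emitted one. Two deliberate refinements:

* *Displacement cap and step adaptation.* The per-step RMS displacement
  is capped at 0.15·ΔRMSD so that emission overshoot stays well inside
  20 % of the target spacing; within the cap the step grows by 1.2× per
  accepted step and is halved (up to 20 times per step, then fatal) when
  a step would raise the energy. Plain fixed steps contract the softest
  modes at a rate s·λ_min per step, which for hinge-like networks
  (condition numbers 10²–10⁴) makes a fixed small step needlessly slow;
  the cap-and-grow scheme is geometrically convergent while keeping the
  trajectory on the steepest-descent path to within the cap.
* *Rigid-body gauge.* The well energies depend only on internal
  distances, so every accepted conformer is rigid-body superposed onto
  the well's reference structure. This is a pure gauge choice — no
  energy or internal coordinate changes — but without it the discrete
  descent accumulates a net rotation (a geometric-phase effect of
  stepping on a rotation-invariant landscape) and terminates at a
  rigidly rotated copy of the end structure; with it the descent lands
  on the end structure itself. The frame adjustment at the start of a
  descent is the residual misalignment of the transition state to that
  well's reference, measured at ~10⁻³ Å on the test fixtures.

Descent terminates when the energy is within 10⁻⁶ kcal/mol of the well's
E0, the RMS force drops below 10⁻⁸ kcal/(mol Å), or the conformer is
within ΔRMSD/2 of the reference structure (at that point no further
image can be emitted and the end structure is appended anyway).

**Pathway assembly.** End structure A, the surface-A images in order of
increasing RMSD from A, the transition state, the surface-B images in
order of decreasing RMSD from B, end structure B. Image indices are
1-based. Consecutive-image RMSD equals ΔRMSD within the displacement cap
except at the endpoints and the transition-state splice, which are set
by where the descent terminates rather than by the emission rule. RMSD
bookkeeping uses the shared frame fixed by the initial superposition of
B onto A (all residues by default, or a user-supplied scaffold subset);
no re-superposition is performed during the search.

**Smoothed potential and string refinement.** E_β is evaluated by
log-sum-exp (no overflow at any β·E) and its force is the
Boltzmann-weighted average of the two well forces. Zero-temperature
string refinement starts from the equal-arc-length redistribution of the
input chain — so that measured drift reflects off-path relaxation rather
than tangential sliding of unevenly spaced input images — and iterates a
steepest-descent step per interior image followed by piecewise-linear
reparametrization; the reparametrization pass is itself iterated to a
fixed point (relative chord-spacing deviation < 10⁻⁸) because a single
pass on a curved chain leaves O(curvature) spacing residuals. Endpoints
are pinned. Divergence (displacement growing ten iterations in a row)
aborts with advice to reduce the step. A finite-spacing string cuts the
corner at the cusp kink, so even at large β the images adjacent to the
transition state move by O(ΔRMSD·kink angle); the drift reported for
large β measures this discretization effect, not a failure of the cusp
path to be a minimum-energy path.

**Normal modes.** The analytic super-element Hessian of a well at its
reference is diagonalized (dense symmetric solver); eigenpairs with
eigenvalue below 10⁻⁸ of the largest are discarded as rigid-body modes
(exactly 6 for a connected, non-degenerate 3D network; more than 6 is
reported as a degenerate network). The cumulative squared cosine
CC(m) = Σ_{q≤m} (d·v_q)²/|d|² measures how much of a displacement the m
lowest modes capture; displacements are superposed onto the reference
end-state before projection so that residual rigid-body components do
not contaminate the profile. CC is non-decreasing and reaches 1 on the
full non-rigid basis for any internal displacement. Where a squared
cosine threshold like "0.90" is quoted it is on the squared (CC) scale;
the un-squared cosine is √CC if needed.

**Non-native contacts.** Residue pairs more than `far` (default 10 Å)
apart in both end-states whose Cα–Cα distance drops below `near`
(default 7 Å; 5 Å is the stricter alternative for compact systems)
somewhere along the pathway. The scan is exhaustive over pairs and
images; distances are Cα–Cα because the model has no other atoms.

**Order parameters.** Segment centroids are unweighted Cα means over
named residue ranges; profiles are centre-of-mass distances between two
segments or the angle at the middle of three segments. Both are
rigid-motion invariant when the transform is applied uniformly to every
image.

## The synthetic fixture generator

`make_toy_two_state` builds a bead chain (3.8 Å virtual-bond spacing,
the Cα–Cα distance) with a central hinge, returning two conformers that
differ only in the hinge angle. Two arm geometries:

* `straight` — planar straight arms; end-to-end distance has a
  closed-form two-arm expression, which makes it the right fixture for
  geometric oracles. Its elastic network is, however, *degenerate*:
  transverse displacements of a straight segment of distance springs
  cost nothing at quadratic order, so the Hessian has far more than 6
  near-zero modes and mode analysis correctly refuses it.
* `helix` — each arm wound as an α-helix-like coil (2.3 Å radius,
  100°/residue, rescaled to keep the 3.8 Å bead spacing). The network is
  densely connected, has exactly 6 zero modes and condition numbers of
  order 10², making it the fixture of choice for mode analysis and
  pathway searches.

A seeded jitter (identical in both conformers) optionally perturbs the
coordinates. The generator emulates a single clean hinge motion between
two well-defined states; it does not emulate the heterogeneous contact
density, multi-domain couplings, unresolved loops or symmetry of real
proteins, so passing tests on these fixtures validate the machinery
(energies, forces, search, assembly, analyses) rather than any claim
about a specific biological system. Runs on experimental structure pairs
(e.g. the adenylate kinase open/closed pair) go through exactly the same
code path and are exercised by an acceptance test whenever the PDB
entries are available.

## Problem sizes

The self-contained test suite and the acceptance script use 2–3-site
analytic systems (closed-form and 0.01 Å-grid oracles) and 12–16-bead
hinge fixtures; at these sizes the full pipeline — transition-state
search, both descents, mode analysis, refinement at two β values —
completes in a few seconds. The engine is O(N²) per energy/force
evaluation with dense O((3N)³) mode analysis, comfortable for
single-chain proteins of a few hundred to ~1000 residues.

## Known limitations

* The cusp makes the energy non-smooth exactly at the most interesting
  point; barrier heights inherit an O(ε₁) uncertainty and the energy
  rise near the transition state is steeper than a smooth two-state
  surface would give. The β-smoothed refinement quantifies this.
* Intermediates whose contact topology differs from both end-states
  cannot appear on a two-well surface built only from those end-states.
* One pathway per end-state pair: the method gives the minimum-energy
  path of this potential, not an ensemble of competing routes.
* No temperature, no kinetics, no free energies — energies are those of
  the knowledge-based network potential.
* Residue matching requires consistent (chain, residue number,
  insertion code) labeling between the two input structures; sequence
  alignment of non-identical constructs is out of scope.
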