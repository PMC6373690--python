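# Methods

This note records the models, conventions and numerical choices behind
`octmatch`, in the spirit of a package's methods appendix: what is
computed, under which assumptions, and what the bundled synthetic fixtures
do and do not demonstrate.

## Error metric and search guarantees

A candidate configuration ⟨S₁…Sₙ⟩ is scored against the target pattern
⟨P₁…Pₙ⟩ by the maximum deviation over **all** unordered vertex pairs,
ε = max_{i<j} ||PᵢPⱼ| − |SᵢSⱼ||, not only over perimeter edges.  The
assembly step therefore enforces all n(n−1)/2 pairwise distances; for a
4-gon all six edge sets are joined even though five independent distances
fix the shape, because the metric itself quantifies over all pairs.

Pairwise distances are blind to reflection, so mirror-image configurations
pass the geometric filter by design; chirality is resolved downstream by
explicit d/l-enantiomer enumeration and the junction-angle check of the
scaffold screen.

Cube-pair pruning and acceptance use the exact worst-case geometry of the
cube diagonal: for cubes of sides l_a, l_b at center distance d, any point
pair deviates from d by at most r = (√3/2)(l_a + l_b), which reduces to
√3·l for equal sides.  Using each cube's own side makes the bounds valid
when a shallow leaf is paired against deeper nodes of the other tree
("self-pairing" a finished branch downward), which is how trees of unequal
depth are synchronized.  Acceptance via the sufficient condition is only
possible when the leaf side satisfies l ≤ ε_T/√3; the builder therefore
rejects minimum leaf sides above ε_T/(2√3) (leaves live in [l_s, 2l_s)).

With l_s = η·ε_T/(4√3), the worst-case radius of a leaf pair is
r ≤ √3·(2l_s) = η·ε_T/2, and a point pair at distance within
(1−η)·ε_T of the target implies a center distance inside the sufficient
window — which is the completeness guarantee: no match within (1−η)·ε_T
is ever lost.  Matches in the outer band ((1−η)·ε_T, ε_T] live in
"boundary" leaf pairs that pass only the necessary condition.  Two
policies are implemented:

* **default (soundness-first)**: boundary pairs are refined by exact
  point-level distance checks, so the returned set is exactly correct on
  both sides of the contract;
* **`cube_approx`**: boundary pairs are dropped wholesale, trading the
  outer band for speed while keeping the completeness guarantee.

The spec of the octree itself leaves two details open, fixed here as
conventions: the root cube is centered on each manifold's bounding-box
centroid but all co-searched trees share one root side l₀ (the smallest
power-of-two multiple of l_s covering the largest bounding box), and
points exactly on a splitting plane go to the higher-index octant.

## Assembly

Per-edge leaf-pair sets are joined by sparse boolean intersection over
cube indices ("matrix product" in spirit, set semantics in practice),
seeding from the edge with the fewest surviving pairs — the standard
selectivity heuristic; enumeration order is deterministic (sorted leaf
paths).  An optional prefilter orients the edge sets around the n-cycle of
trees and keeps only strongly connected components that touch all n
groups; a valid n-tuple traces a directed n-cycle, so the filter is safe
(verified against unfiltered runs in the tests).  Representative points
are the first qualifying tuple in a deterministic scan; an
exhaustive-points mode enumerates all qualifying point tuples.

Per-edge tolerance overrides are deliberately *not* implemented as an
energy weighting: no defensible weighting formula presents itself for the
geometric layer, so weighting is left to downstream refinement tools.

## Scaffold screen

For m take-off sites and an n-residue pattern the screen enumerates
C(m,n) site combinations × 2ⁿ enantiomer assignments (the familiar
4 triangles → 32 search instances for m=4, n=3).  Mirroring reflects a
residue's side atoms through the plane of its three backbone atoms, an
involution that preserves all within-residue distances.  The vertex
correspondence between a site combination and the hotspot stubs is
resolved inside one search instance by scanning the n! orderings and
keeping the best-scoring survivor per instance.

Junction angles ("CheckAngle") are measured on the *placed* scaffold:
for each matched residue, the angle at a named scaffold atom (e.g. Cα)
between a second scaffold atom (e.g. N) and the stub's connect-atom
position.  Survivors require every such angle within δ_A of its declared
optimum.  δ_A defaults to 0.2 rad — a convention borrowed from the loop
tolerance, as the screen itself fixes no number — and δ defaults to the
search tolerance ε_T.  Matches are ranked by shape_rmsd² + w·angle_rmsd²
with w = 1 Å²/rad² by default; superposition is restricted to proper
rotations because the transform is applied to a physical scaffold.

When a stub declares a manifold of attachment positions (flexible side
chains), the polygon comparison routes automatically through the
octree search over those manifolds instead of the fixed-point fast path.

## Loop closure

The residue model is a three-atom N–Cα–C abstraction with **uniform**
bond length (1.5 Å) and bond angle (111°), consecutive residues sharing
their junction atom.  Uniform geometry is a deliberate simplification
with a structural payoff: a chain read backwards obeys the same
internal-coordinate model with the torsion pair of each residue swapped,
so a product grid of torsion values represents both semi-loops of one
closed loop exactly.  This is what lets the closable-loop fixture plant a
ground truth that is *guaranteed representable* by the search's own
conformation table.

Growth states are collapsed per (lattice cube of the chain end,
direction bin of the last bond).  Direction bins are uniform
polar/azimuth bins of width angle_tol/2 — tied to the tolerance so that
collapsing cannot merge states whose later angle checks differ by more
than the tolerance itself.  A pivot's take-off vector alone does not fix
the torsional reference of the first placed atom, so `LoopSpec` accepts
optional explicit three-point anchor frames; absent those, a canonical
anchor is constructed deterministically from (pivot, take-off) such that
a zero first torsion sends the first bond along the take-off vector.

Mid-loop matching requires the two semi-loop ends to share a lattice
cube; candidate state pairs are screened by the exemplar junction angle
(with slack for the discretization) and then *every backtracked loop is
re-instantiated exactly from both pivot anchors and re-measured*: all
junction bond angles within angle_tol and the midpoint gap within one
cube diagonal.  Only loops passing this exact final filter are emitted,
so validity of the output does not depend on the binning heuristics.
Predecessor links retain all parents per collapsed state (exhaustive
backtracking); the collapse is therefore an enumeration-sharing device,
not an approximation of reachability.

What "recovering the planted loop" can mean deserves care.  Collapsed
states store one exemplar's coordinates, and transitions are recorded
from exemplars, so for *degenerate* conformation tables the planted
loop's exact coordinate trajectory can drift out of the enumerated set —
an approximation inherent to discretized bidirectional closure.  With
the fixture's default tables (16 grid conformations, 0.4 Å cubes) exact
atom-for-atom recovery holds across all tested seeds for k = 4–8 and is
asserted in the tests; for longer loops (k = 10–12, run with reduced
4-conformation tables) the tests assert the weaker, honest property:
the planted instance is solved and every emitted loop is valid under
independent re-measurement.

The reference experiment in the field uses Mr = 1000 conformations and a
121³ lattice of 0.1-unit cubes with 0.2 rad angle tolerance; those remain
the documented defaults of the CLI's parameter space, but tests and the
acceptance script run far smaller tables (Mr ≤ 16) and lattices so the
whole suite completes in minutes on one CPU.

## Synthetic fixtures: what they show and what they do not

* `plant_polygon` hides one perturbed vertex copy (each vertex moved by at
  most noise/2, keeping the planted tuple's ε within the noise budget)
  among uniform decoys in a box defaulting to 10× the pattern diameter.
  Uniform decoys exercise pruning at many levels but have none of the
  shell-like radial structure of real dihedral-sweep manifolds; passing
  tests demonstrate the search contract, not performance on rotamer-like
  density.
* `make_toy_scaffold_library` builds 4-site scaffolds with one exact
  rigid copy of the stub geometry (junction angles constructed at
  optimum) — a known answer that must score 0/0 and rank first.  Decoy
  scaffolds are random, not chemically plausible backbones.
* `make_closable_loop` plants a grid-representable closed loop and emits
  its pivots, take-offs and anchor frames; recoverability is by
  construction, as discussed above.

## Problem sizes used by tests and the acceptance script

Chosen to keep a single-CPU run in minutes while still averaging over
enough randomness to be meaningful: oracle-equivalence runs 54 planted
fixtures (9 tolerance-grid cells × 6 seeds) at N = 300 points per
manifold; pruning statistics average 60 random octree pairs at N = 250;
loop closure runs k ∈ {4, 6, 8, 12} with the tables above.  All
randomness is routed through explicit integer seeds; every generator is a
pure function of (parameters, seed).

## Known limitations

* The adaptive search is pure Python over tree nodes; it is meant as a
  clear reference implementation, not a performance benchmark.
* No clash checking, energies, or refinement: the geometric screen is the
  first stage of a design pipeline and deliberately stops there.
* The loop model's uniform-geometry abstraction does not distinguish
  N–Cα from Cα–C bonds; mapping results onto real peptide geometry
  requires a refinement step.
* PDB is the only structural format (no mmCIF); altloc handling keeps the
  first conformer.
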