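# Methods

`cgrna` samples RNA 3D conformations at helix resolution, guided by a
small-angle X-ray scattering (SAXS) pair distance distribution (PDD), and
checks/repairs the topology of the resulting coarse-grained models.  This
note records the model, the defaults that matter, and the design choices
made where the design was genuinely open.

## Coarse-grained model

The secondary structure (dot-bracket, non-pseudoknotted, single chain) is
decomposed into elements: stems, hairpin loops, interior loops (bulges
included), multiloop segments and 5'/3' terminal strands.  A stem is a
rigid body parametrized by its axis endpoints, its length in base pairs and
a unit vector (`twist_ref`) giving the groove orientation at its first base
pair.  Assuming each base pair contributes equally to the helix rotation,
per-residue virtual points — backbone phosphate (P), sugar/C1' proxy (S)
and base (B) — are reconstructed on the fly from A-form constants:

| parameter | default | meaning |
|---|---|---|
| twist | 32.7 deg/bp | helical rotation per base pair |
| rise | 2.81 A/bp | axial spacing of base pairs |
| r_P, r_S, r_B | 9.4, 8.5, 4.0 A | radial offsets of the three points |
| strand angle | 150 deg | angular offset of the paired strand |

These constants set absolute distances (and therefore absolute PDDs) but
not the algorithmic behaviour; all are configurable via `HelixParams`.

Loop elements carry rigid *fragments*: a fragment is the 4x4 transform
between the attachment frames of the flanking stems, keyed by a signature
(element kind, per-strand unpaired lengths).  A structure is assembled by
placing a root stem at a canonical pose and composing fragment transforms
along the spanning tree of the element graph.  Loop residues themselves are
interpolated on straight lines between their flanking stem anchors (real
loop fragments carry internal geometry we do not reproduce); terminal
strands extend outward at 5.9 A per residue.

**Multiloop closure.**  A k-way junction has k single-stranded segments but
only k-1 degrees of freedom: once the others are placed, the last segment
(the *broken* segment — here, by convention, the one whose 5'-most position
is largest) is determined.  Its fragment is not sampled; it is fitted by
scanning the library for the transform that best closes the junction cycle.
The closure deviation between the placed and recomposed stem pose is
summarized as `scalar = translation + w * rotation`, with w = 10 A/rad; a
conformation is accepted only if `scalar <= 6 A` (hard threshold), and a
harmonic penalty `k_ml * scalar^2` enters the energy.  The combined scalar
and its weight are this package's own metric; any monotone combination of
the translational and rotational mismatch with a zero fixed point would
serve.

**Clashes.**  Virtual points of elements that are not neighbors in the
element graph may not come closer than 4.0 A; clashed structures have
infinite energy.  Graph neighbors (a loop and its flanking stems) are
exempt because their points legitimately abut.

## PDD energies

The target PDD is read as a two/three-column `r P(r)` curve (the format in
which GNOM-style indirect-transform output is conveniently re-exported),
interpolated onto an equal-width grid (default 1 A) and renormalized.  The
model PDD is the normalized histogram of all pairwise distances between
scattering centers — either one per residue (S point) or three per residue
(P, S, B); the hydration shell is neglected.  Structures whose extent
exceeds the target's d_max are infeasible: they cannot carry mass inside
the target support.

Two pseudo-energies are implemented, both with the correct fixed points:

* **Area energy** `E = k * TV(p, target)`: k times the total-variation
  distance (half the L1 area between the curves).  Zero iff the structure's
  own PDD equals the target; a single-structure potential.
* **Reference-ratio energy** `E = -k * sum_b p(b) ln[(target(b)+eps) /
  (q(b)+eps)]`, where `q` is the PDD of the *sampled ensemble*.  Bins the
  ensemble underpopulates relative to the target are favored for structures
  that occupy them; when the ensemble distribution matches the target the
  energy vanishes identically, so there is no residual force at
  convergence.  The ensemble histogram decays exponentially (lambda = 0.99
  per update; an effective memory of ~100 structures) so early, unconverged
  history is forgotten; it is never reset.  `eps = 1e-6` stabilizes the
  log-ratio while bins are still empty.

## Sampling

Metropolis sampling over fragment assignments, with `min(1, exp(-dE/T))`
acceptance (k_B = 1, energies dimensionless).  Move kinds and default mix:

* `single` (0.4) — replace one loop's fragment;
* `pair` / `triple` (0.2 / 0.2) — jointly replace 2 / 3 connected segments
  of one multiloop, opening paths around the forbidden regions that the
  clash and closure constraints carve out of the state space;
* `exchange_relax` (0.2) — one replacement followed by a greedy pass over
  the junction neighbors, re-selecting each to lexicographically minimize
  (clash count, summed closure deviation); the objective never increases.

Kinds that cannot apply (pair moves without a junction) are redrawn.  After
every accepted move the broken segment of each junction is re-fitted.  In
reference-ratio mode the ensemble is updated each step with the *retained*
state's PDD — the correct Monte-Carlo ensemble average, re-counting the
current state when a proposal is rejected.  Initialization is rejection
sampling of a feasible random assignment (up to 1e4 retries).  Temperature
is constant (default 1.0) or a linear annealing schedule (default 10 to 0.1
when enabled).

## Topology: link detection and removal

Assembled fragments can leave secondary-structure elements entangled.
Hairpins, stems and closed junctions are represented as closed rings
through their consecutive P and S beads plus the closing base pairs;
interior-loop strands and exterior inter-stem segments, which cannot close,
become open probes.  Two detectors are combined:

* **Gauss linking number** L of two rings, evaluated with the exact
  analytic segment-pair solid-angle formula for polygonal curves (Klenin &
  Langowski 2000) — the numerically robust equivalent of integrating the
  Gauss double contour integral along the segments.  |L| >= 1 (rounded,
  residual < 0.05; larger residuals are annotated for review) means linked.
  Exactly coplanar or parallel segment pairs contribute zero solid angle
  and are zeroed explicitly.
* **Piercing counts** through the triangle fan spanned by consecutive ring
  vertices and the ring centroid.  The signed sum (net) detects links —
  including probe-through-ring cases no ring pair can express — while a
  nonzero *gross* count with zero net flags interpenetration, which the
  Gauss integral cannot see.  Grazing segment-triangle incidences are
  retried once with the segment offset 1e-5 A along the triangle normal
  (deterministic, geometrically negligible, and large enough to clear the
  1e-9 incidence classification band); anything still ambiguous raises a
  geometry error that is annotated per pair, not fatal.

The fast piercing method is the primary detector; both methods together are
the post-relaxation confirmation gate.

**Link removal** is a restrained Monte-Carlo relaxation on the beads, run
in detect->repel rounds (default 20 rounds within a 2e5-step budget).  Each
round re-runs the detectors, rebuilds the rings from the current beads and
repels the beads of every offending pair from *virtual sites* sampling the
partner ring's entire enclosed surface (centroid, mid-radius points, rim
vertices; flat-bottom repulsion k_rep = 10, r_c = 8 A).  Centroid-only
sites were tried first and cannot remove a threaded stem: the radial push
moves beads along the ring normal but never past the rim.  Two further
ingredients make removal reliable:

* a *directed escape* term pushing each offending element to the side of
  the partner ring's best-fit plane where most of its beads already lie
  (within the ring's lateral footprint) — without it, a symmetric push can
  shove one arm of an interpenetrating element *through* the ring and
  create a genuine link;
* beads of graph-adjacent elements move too, under restraints only, so
  chain bonds at element boundaries follow instead of stretching.

All beads are tethered to their input positions (k_pos = 0.1 A^-2) and
consecutive backbone beads are bonded harmonically to their input lengths
(k_bond = 2 A^-2) with a hard wall keeping every bond within [0.5x, 2x] its
input length — chain connectivity is preserved by construction.  Bead moves
are Gaussian (sigma = 0.5 A) with temperature annealed 1.0 -> 0.01 within
each round; after the detectors first report clean, a low-temperature
settle pass relaxes transiently stretched bonds before the final
confirmation.

## Synthetic data

No external dataset is required; the `fixtures` module generates every
study input programmatically and reproducibly:

* canonical ring configurations (Hopf link, separated rings, a double
  winding, seeded random ring pairs with a minimum separation of 0.5 A);
* bead geometries for a stem genuinely threaded through a hairpin ring and
  for an interpenetrating (net-zero crossing) pair, each attached to a real
  two-hairpin secondary structure;
* a three-way junction whose broken segment's exactly closing fragment is
  planted in a synthetic library among random decoys;
* a two-stem sampling system whose target PDD is computed from a designated
  (planted) library fragment.

Synthetic fragment libraries draw rotations uniformly over SO(3) and
translation norms uniformly in [3, 25] A (bulge-to-extended-loop range).
These fixtures emulate the geometry and topology of assembled RNA models
but not their sequence-dependent detail: loop beads are idealized
placements, libraries are random rather than mined from solved structures,
and energies are exercised at toy scale (24-nt systems, hundreds to
thousands of Monte-Carlo steps — sizes chosen so the full suite exercises
every code path in minutes).  Passing tests therefore demonstrate the
correctness of the algorithms and their fixed points, not prediction
accuracy on real RNAs, which additionally depends on fragment-library
quality and experimental PDD estimation (in particular the d_max chosen in
the indirect transform, which is delegated to upstream tools).

## Numerical choices and degenerate inputs

* Rotation matrices are validated to be proper orthonormal (1e-9 scale
  tolerances); closure rotation angles come from the trace formula with
  clipping, so angles near zero are accurate to ~1e-6 rad.
* PDD bins are half-open `[i*w, (i+1)*w)`; curves must sum to 1 within
  1e-9.
* Rings must have >= 3 vertices with consecutive vertices > 1e-9 A apart
  (consecutive duplicates from zero-length segments are dropped); ring
  pairs with vertices closer than 1e-6 A are rejected as degenerate.
* Ties in the broken-fragment argmin are broken by `source_id`, making the
  fit deterministic.
* Zero-length multiloop segments are real elements with empty residue
  lists, so they can carry fragments and participate in closure.

## Known limitations

* Non-pseudoknotted, single-chain secondary structures only.
* Loop residues are interpolated, not modeled; sequence-dependent helix
  geometry and non-canonical pairs (3D motifs) are out of scope.
* Knot detection within a single chain is not attempted; the detectors act
  on element pairs.
* The untangling energy is the restrained repulsion model above, not a
  force field; it repairs topology, not local geometry.
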