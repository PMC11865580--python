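# Methods

## Solvent-accessible surface area and interface definition

Per-atom SASA uses the Shrake–Rupley construction: each heavy atom carries a
sphere of radius r_vdw + r_probe sampled at `n_sphere_points` directions, and
a direction is accessible if its point lies outside every neighbour's
enlarged sphere. Hydrogens are ignored and reported with area 0.

* **Probe radius** 1.4 Å (water); exposed as a parameter.
* **Sampling** is a golden-section spiral, not random sampling. The point
  set is identical for every atom and every invocation, which makes results
  reproducible without seeds and makes occlusion *monotone*: adding atoms
  can only remove accessible points, so every apo-minus-holo difference
  (dSASA) is non-negative exactly, not just statistically. The default of
  960 points reproduces the analytic isolated-atom area to machine
  precision and agrees with a 3840-point computation to < 2 % of the
  isolated-atom area per atom. Per-atom deviations are quoted against the
  isolated-atom area because the self-relative error of a nearly buried
  atom is dominated by its vanishing denominator.
* **Consequence of fixed sampling:** a rigid rotation of the molecule
  rotates the structure relative to the (space-fixed) point pattern, so
  SASA is rotation-invariant only to sampling accuracy (observed ≲ 0.3 %
  per atom, tested at 1 %). Exact invariance would require an analytic
  method (Lee–Richards), which is out of scope. All purely geometric
  quantities downstream (sphere fits, signs, RMSD) are exactly invariant.
* **vdW radii** are the Chothia-style values distributed with NACCESS
  (C 1.87, N 1.65, O 1.40, S 1.85, P 1.90 Å, element-level fallback
  1.80 Å), pinned in `structure_io.VDW_RADII` and overridable per call.
  Published buried-area values computed with other radii sets can differ by
  a few percent; the radii choice is reported rather than tuned.
* **Interfacial atoms**: heavy atoms with dSASA ≥ 0.5 Å², where apo SASA is
  computed on the partner's atoms extracted from the complex coordinates
  (no re-relaxation) and holo SASA on the union, with identical sampling.
  Membership is atom-level; a residue-level view (≥ 1 interfacial atom) is
  provided for reporting. Buried area is the dSASA sum split by element
  polarity (N, O polar; C, S apolar), summed over both partners with a
  per-partner breakdown.

## RANSAC sphere fit and signed convexity

A sphere is the minimal shape summary of a binding patch; its reciprocal
radius is the patch's curvature magnitude.

* **Hypotheses** are exact spheres through 4 sampled points (the minimal
  determining set), solved by a closed-form 3×3 linear system. Samples
  whose system has a Frobenius-estimate condition number above 1e8
  (near-coplanar quadruples) are rejected but still consume iterations.
* **Consensus**: points within 1 Å of the candidate surface (|distance to
  center − radius| ≤ threshold). The candidate with the most inliers wins;
  ties break by smaller inlier RMSE, then earlier iteration, making the
  result a deterministic function of the seed. Default budget 10⁵
  iterations with an early exit when a candidate explains every point.
* **Refinement**: the winner is refit by algebraic least squares
  (linearised ‖x‖² = 2c·x + (r² − ‖c‖²)) on its inliers, and the inlier set
  is re-classified once after the refit. The refit shifts the radius
  slightly; it is documented because the same brute-force selection rule
  (all 4-subsets enumerated) is used as the test oracle and must agree.
* **Sign**: with g_p the centroid of the partner's heavy atoms, g_i the
  centroid of the interfacial atoms and c_s the fitted center, the patch is
  concave iff (g_p − g_i)·(c_s − g_i) < 0 — both vectors are rooted at the
  patch centroid, so a pocket (center on the solvent side, body on the
  other) is negative. A zero inner product raises an explicit
  indeterminate-sign error rather than guessing. The reported convexity is
  sign/radius in 1/Å.
* Fits use interfacial heavy-atom coordinates directly, without dSASA
  weighting.

## Scaffold screening

Helix assignment is dihedral-based: a residue is helical when φ ∈ [−100°,
−30°] and ψ ∈ [−80°, −5°] (chain-terminal residues are judged on the
dihedral they have); lone gaps flanked by helical residues are closed
(runs are never extended past their flanks) and maximal runs of ≥ 6
residues become segments. The windows are deliberately generous — they
accept ideal α-geometry (−57°, −47°) with > 20° of margin — and are
module-level constants. DSSP-style hydrogen-bond assignment is not used;
the dihedral rule needs no external binary and is exact on the generators.

Admission rules (all verdicts reported even when one fails): exactly 5
helices; ≤ 119 residues total; face helices (odd-numbered, H1/H3/H5, 1-based,
overridable) each 18–22 residues; concave face. The face is summarized by
Cβ atoms (Cα for glycine) of face-helix residues whose Cα→Cβ direction has
cosine > 0.5 with the open-face direction (the bundle-axis-orthogonal
component of the vector from the bundle Cα centroid to the face-helix Cα
centroid). The cosine threshold keeps the selected shell radially
consistent; lowering it toward 0 admits tangentially pointing side chains
whose spread (0–3.3 Å in radial offset) degrades sign recovery on gently
curved faces. Both the threshold and the face indices are parameters.

## Synthetic generators

The generators exist so the screening rules and the sign test are testable
end to end; they do not model physical backbone assembly.

* **`make_toy_bundle`** places ideal α-helices (NeRF-built backbone + Cβ,
  φ = −57°, ψ = −47°, rise 1.5 Å/residue) antiparallel in two rows: face
  helices in front, buttressing helices 10 Å behind. For non-zero face
  curvature the helix axes lie on a sphere of radius 1/|curvature| and are
  bowed along their length on that same sphere — with straight helices the
  face shell would have infinite curvature radius along the helix axis and
  a sphere fit to it would be ill-posed. Negative curvature produces a
  concave face, positive convex, zero a flat row. Loops are geometric
  placeholders built by NeRF continuation with extended torsions
  (φ = −150°, ψ = +150°): every loop residue owns at least one dihedral far
  outside the helical windows, and two anchor placements keep the flanking
  helix residues' φ/ψ exactly helical, so helix segment lengths are exact
  by construction. The loop is not required to close the chain. A Gaussian
  coordinate jitter (σ = 0.05 Å) varies fixtures across seeds while staying
  ≫ 5σ inside the dihedral windows. Defaults (5 helices × 19 residues,
  loops of 3, 107 residues total, spacing 10 Å) represent a typical small
  concave bundle.
* **`make_ball_socket_complex`** docks a convex pseudo-atom ball (golden-
  spiral shell, radius 6 Å) into a concave two-layer cap shell (radius
  11 Å, 60° half-angle). It exercises interface detection and gives
  ground-truth signs (+1 ball, −1 socket) and radii.

What the generators do **not** emulate: side chains beyond Cβ, packing
cores, loop closure, sequence–structure consistency, crystallographic
disorder, or the atom-density heterogeneity of real interfaces. Passing
tests therefore demonstrate correctness of the geometry pipeline, not
accuracy of convexity values on deposited structures, where radii-set and
model-vs-crystal differences add a few percent of spread.

## SSM statistics

Counts are the input boundary (read merging/alignment is out of scope).
Enrichment is log₂ of whole-pool-normalised frequencies,
f = (count + α)/Σ(count + α) with pseudocount α = 1 by default — the
standard deep-mutational-scanning convention; base, normalisation and
pseudocount are parameters. Entropy is computed from selected-pool
frequencies (not from enrichment values), with 0·log 0 := 0, bounded by
[0, log₂ 20 ≈ 4.3219 bits]; an all-zero position with zero pseudocount is
an explicit error naming the position. Conservation classes are entropy
quantiles within the profile (strictly below the low quantile = conserved,
strictly above the high = variable), so a constant profile collapses to
all-intermediate. Parent-residue cells are retained by default (wild-type
synonym reads); a masking flag is available in the matrix container.

The sorting simulator draws a reference pool from a Dirichlet-multinomial
per position and reweights by per-variant log-normal fitness (conserved
positions penalise all substitutions to 5 % of parent fitness). At 10⁴
reads/position the rank correlation between assigned fitness and recovered
enrichment exceeds 0.9, which is the regime the defaults represent.

## Degenerate-codon library design

All 15³ = 3375 IUPAC triplets are expanded against standard genetic code
table 1 (no organism-specific codon usage). Covering codons (encoded set ⊇
desired, stop-free unless permitted) are ranked by fewest off-target
distinct amino acids, then smallest DNA degeneracy, then lexicographic
triplet — the selection objective is a package convention, documented
because several orderings are defensible. `build_library` takes the
top-ranked codon per position; DNA diversity (Π degeneracies) is compared
against the 10⁷ transformation capacity because transformation limits act
on DNA molecules, while protein diversity is reported alongside. Desired
sets must include the parent residue by default (relaxable), reflecting
combinatorial libraries that keep the parent identity available.

Design-metric filtering applies ddG ≤ −40, contact molecular surface
≥ 400, pAE ≤ 10 (optionally mean plDDT ≥ 80) in order; thresholds are
inclusive, rows exactly on a bound pass but are counted in a `boundary`
flag, and missing values fail their rule and are counted separately. The
survivor set is order-invariant; attrition counts are not.

## Superposition and identity

Kabsch superposition via SVD with a determinant sign correction on the
smallest singular direction, so only proper rotations are returned and
protein chirality is preserved. Cα RMSD pairs residues by ungapped-style
global sequence alignment (match 1 / mismatch 0 / gap −1) by default, or by
residue number; the scheme and atom count are always reported because
published RMSD values depend on the pairing. Sequence identity divides
matches by length (ungapped, equal lengths required, 2-decimal reporting)
or by alignment columns (global); `X` never counts as a match.

## Numerical choices and degenerate inputs

* Condition estimate for 4-point samples: ‖A‖_F·‖A⁻¹‖_F with the inverse
  from the closed-form adjugate — cheap enough for 10⁵ batched hypotheses.
* Coplanar/collinear point sets, < 4 points, empty centroids and zero
  inner products all raise typed exceptions rather than returning NaN.
* Interface profiles degrade gracefully: a partner with < 4 interfacial
  atoms yields a null convexity with a warning, not a failure.
* All randomised operations take an explicit integer seed (default 0);
  RANSAC results are bit-for-bit reproducible given the seed.

## Problem sizes

The test suite and the acceptance script run on synthetic inputs sized for
interactive use: bundles of ~420 atoms, interfaces of ~80–190 pseudo-atoms,
RANSAC budgets of 3 000–100 000 iterations, SSM tables of 20 positions ×
10⁴ reads, and 30 + 10 scaffold screens per invariant. These sizes were
chosen so each property is measured with comfortable statistical margin;
the same code paths handle deposited complexes of a few thousand heavy
atoms with the default 10⁵-iteration budget.

## Known limitations

* SASA is sampled, not analytic; see the rotation-invariance note above.
* Helix assignment is dihedral-only and will disagree with DSSP near
  helix caps and π-bulges.
* The toy-bundle loops do not close the chain; bond geometry across
  helix–loop junctions is intentionally non-physical.
* Convexity of very gently curved faces (|c| ≲ 0.01 1/Å) approaches the
  flat limit where the fitted radius, and hence the sign, becomes
  ill-conditioned; results there should be read as "approximately flat".
* External design metrics (ddG, contact molecular surface, pAE, plDDT) are
  consumed as data, never computed.
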