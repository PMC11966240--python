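# Methods

## Invariant definition

A protein chain is reduced to its main-chain trace: atoms N, Cα, C of each
of its *m* residues (the carbonyl O carries no extra rigid-shape
information for this purpose and is excluded). Each residue defines a
right-handed orthonormal frame from its own three trace atoms:

    origin = Cα
    e1 = unit(N − Cα)
    e3 = unit((N − Cα) × (C − Cα))      # normal of the N–Cα–C plane
    e2 = e3 × e1

The frame exists whenever the three atoms are not collinear (guarded at
‖cross‖ > 1e−6 Å²; real backbones sit far from this limit, the guard is for
synthetic edge cases). The frame is continuous in the atom positions,
equivariant under rigid motion, and flips handedness under reflection.

Row *i* (for *i* ≥ 2) of the invariant matrix holds the local coordinates
of residue *i*'s N, Cα, C in the frame of residue *i* − 1, columns grouped
per atom as (x′, y′, z′). Row 1 holds residue 1's atoms in its own frame,
which forces the pattern `(|N−Cα|, 0, 0, 0, 0, 0, (C−Cα)·e1, (C−Cα)·e2, 0)`
with the eighth entry strictly positive (Cauchy–Schwarz, non-collinearity).
This convention keeps the matrix exactly m×9, rigid-invariant, continuous,
and retains residue 1's internal geometry. Alternative but equivalent frame
conventions exist; all contracts tested here (invariance, invertibility,
subchain containment, mirror behavior) are convention-independent.

Chains need m ≥ 2: a single residue has no predecessor frame, so such
chains are rejected rather than given a degenerate 1×9 matrix.

**Inversion.** Residue 1 is placed in the canonical pose (Cα at the origin,
N on +x, C in the xy-plane with positive y); each later residue is placed
from its row in the frame built on the previously reconstructed residue.
This is exact up to floating-point error: round-trip RMSD after optimal
superposition is at machine precision (asserted at ≤ 1e−8 Å over chains up
to m = 200).

**Mirror images.** Point reflection flips every frame's e3, so the z′
columns (3, 6, 9) change sign for rows ≥ 2 while row 1's chirality-bearing
entries are structural zeros. A backbone equals its mirror exactly when
those columns vanish (planar backbone); helical fixtures sit > 2 Å from
their mirrors in the invariant metric.

**Averaging.** The Brain vector is the arithmetic mean of the nine columns,
all rows weighted equally, fixed summation order (bitwise reproducible).

## Metric and the cascade

Both matrices and Brain vectors are compared under the Chebyshev (L∞)
metric: the maximum absolute componentwise difference. This choice makes
the prefilter inequality a theorem rather than a heuristic: for equal m,

    max_k |mean_i a_ik − mean_i b_ik| ≤ max_{i,k} |a_ik − b_ik|,

so Brain distance never exceeds BRI distance, and discarding pairs with
Brain distance > t cannot lose a pair with BRI distance ≤ t. The scan is a
three-stage cascade — bucket by m (integer invariant), Brain prefilter,
BRI confirmation — whose output provably equals the brute-force all-pairs
BRI scan; the test suite verifies this equality on randomized corpora with
planted borderline pairs straddling t.

The prefilter is implemented as a sort on the first Brain coordinate with
a sliding window of width t followed by the full 9-coordinate Chebyshev
check: an exact range query (any pair farther than t in one coordinate is
safely skipped), which preserves the no-false-negative contract at desk
scale without an auxiliary index structure.

Confirmed pairs within one deposition are excluded by default
(`exclude_same_entry`), since chains of the same entry legitimately repeat
coordinates; a flag restores them.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| duplicate threshold t | 0.01 | Å | confirmed duplicate pairs in curated comparisons show max atom deviations ≤ 0.003 Å; 0.01 Å separates those from genuinely distinct refinements by orders of magnitude |
| max_resolution | 4.0 | Å | scoping rule for crystal structures worth manual triage |
| min_residues | 2 | — | smallest chain with a defined invariant |
| occupancy rule | any atom | — | strictest reading: any partial occupancy or altloc disqualifies the chain; a policy flag restricts the rule to main-chain atoms |
| completeness | N, Cα, C | — | the atoms the invariant uses; missing carbonyl O is logged, not rejecting (policy-extendable) |

## Forensic pair statistics

`max_dev` is the largest Euclidean distance between corresponding trace
atoms **without superposition**: true redepositions share the deposited
coordinate frame, and the diagnostic mÅ-scale offsets (e.g. a uniform
0.001 Å shift of every x coordinate) vanish under superposition. A
`--superpose` option reports the Kabsch-superposed deviation alongside,
never instead. `n_diff_res` counts positions whose amino-acid codes differ
— the signature of relabeled coordinate copies. Chain pairing is
positional (residue k to residue k); all chain-vs-chain combinations of
equal m between two entries are reported separately.

## Chain cleaning

A chain is rejected under exactly one category, in rule order: no standard
amino acid at all (nonprotein); any partial occupancy or altloc
(partial_occupancy); non-consecutive residue numbers or insertion codes
(nonconsecutive_numbering); an interior residue missing N/Cα/C
(missing_mainchain — incomplete *terminal* residues are trimmed and the
chain kept); any residue outside the canonical 20 (nonstandard_residue;
MSE counts as nonstandard unless the policy whitelists it); fewer than
min_residues after trimming (too_short). Waters are dropped before
classification so a protein chain with attached solvent is not
miscategorized. Only the first model of multi-model files is read. The
report preserves one outcome per input chain, so category counts always
sum to the number of chains.

Entry-level scoping: resolution must be present and ≤ the cut-off, and
entries flagged as group depositions (bulk submissions with intentionally
near-identical coordinates) are excluded before any comparison.

## Synthetic data

The fixture generator emits ideal-geometry helical backbones: a template
residue with exact bond lengths (N–Cα 1.458 Å, Cα–C 1.525 Å) and N–Cα–C
angle (111.2°), propagated by a screw motion (twist ~99°, rise ~1.5 Å,
radius 2.3 Å, all configurable), placed in a seeded random pose. Because
consecutive residues are related by a fixed rigid motion, all invariant
rows beyond the first are identical — a sharp oracle for the computation.
Corpus emission jitters twist and rise per chain so equal-length chains
are far apart, and writes each entry as a PDB file and an mmCIF twin with
fabricated headers (resolution, R_free, optional group-deposition flag).

Planted duplicates: exact copies; relabeled copies (k codes changed,
coordinates untouched); rigid-motion copies; and "perturbed" copies
realized as uniform 0.001 Å axis translations — the offset confirmed
near-duplicate redepositions actually exhibit. A uniform translation is
rigid, so these pairs have BRI distance zero while their max_dev is
exactly the planted shift; recall of all four categories is therefore
exact, not statistical. Decoys that must never be reported: mirror images
and far-perturbed copies (per-atom jitter of 0.1 Å, an order of magnitude
above t).

Emitted coordinates are snapped to the 0.001 Å grid (the PDB format's
precision) before planting, and planted rigid motions are grid-compatible
(cube rotations + whole-mÅ translations), so ground truth survives file
round-trips exactly and a fixed seed reproduces a corpus byte for byte.

What the generator does **not** emulate: Ramachandran-realistic torsion
distributions, side chains, solvent, crystallographic disorder, or
experimental coordinate noise between independent refinements. Passing
tests therefore demonstrate the correctness of the invariant and the
exactness of the cascade, and the behavior of the filters on the defined
categories — not retrieval statistics on real repository data, where the
interesting failure modes are metadata quality and scale.

Per-atom random perturbation (uniform in the ball of radius δ, so bounds
are hard rather than probabilistic) remains available for the continuity
suite: the measured response is linear, with an empirical amplification
factor of roughly 5–7 between atom displacement and worst BRI entry change
for these fixtures (theory guarantees existence of such a constant, not a
value; it grows with inter-atom distances since a frame tilt of order
δ/bond-length displaces atoms ~3.8 Å away proportionally). This is why a
per-atom jitter below t does not, in general, keep the BRI distance below
t — and why near-duplicate thresholds should be read in the invariant
metric, not the coordinate metric.

## Numerical choices

- All tolerances assume 64-bit floats. Rigid invariance and
  mirror/reflection identities are asserted at 1e−9 Å; frame orthonormality
  at 1e−10; reconstruction round-trips at 1e−8 Å RMSD.
- Subchain containment is asserted bitwise (exact `==`): interior rows of a
  subchain's invariant are computed from identical inputs by identical
  arithmetic.
- Rotation validity: orthogonality within 1e−10 and det = +1 within 1e−9;
  reflections are rejected (`ImproperRotation`) so mirror images can never
  superpose silently.
- Kabsch superposition delegates to SciPy's `Rotation.align_vectors`
  (proper rotations only) and is used in tests and the optional superposed
  deviation — never in the duplicate decision itself.
- Occupancy comparison uses a 1e−6 tolerance below 1.0.
- Degenerate frames report the 1-based residue index; cleaning never
  raises — every problem is a report category.

## Problem sizes

The randomized suites use 20 fixture chains (m up to ~80) × 100 rigid
motions for invariance, 50 chains with m ∈ [2, 200] for inversion, and 20
corpora of ~60 chains with planted borderline pairs for the
cascade-vs-brute-force equality; the file-level recall corpus plants one
duplicate per category among 10 base entries plus filter-violating and
decoy entries. These sizes exercise every code path and keep the whole
suite in a few seconds; the cascade's asymptotic advantage over brute
force is architectural (bucketing + 9-coordinate prefilter) and is not
benchmarked here.

## Known limitations

- Chains are compared only at equal residue count and by positional
  pairing; duplicated *subchains* (the hereditary property makes the rows
  directly comparable) are not searched.
- Group-deposition detection relies on the keyword text of the header;
  repositories encode this flag in several ways.
- R_free extraction covers the standard REMARK 3 line and the mmCIF
  `_refine` tag; exotic headers yield a missing value (reports still
  work).
- Entries without resolution metadata are conservatively out of scope.
- Metadata forensics beyond the coordinate statistics (data-collection
  narratives, B-factor patterns, unit-cell consistency) are out of scope;
  the reports surface the numbers a curator needs to start that manual
  review.
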