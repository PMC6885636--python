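# Methods

This note documents the models and procedures implemented in
`gcensemble`, the parameter choices that matter, and what the synthetic
benchmarks do and do not demonstrate.

## Structures and selections

Ensembles are read from multi-model PDB files, one frame per MODEL, all
models required to share an identical atom-identity sequence
(chain, author residue number, atom name) after alternate-location
resolution. The altloc policy keeps the highest-occupancy conformer,
breaking ties toward the lexicographically smallest altloc code, so
parsing is deterministic. Hydrogens are read and only excluded at
selection time — contact analysis must provably ignore them rather than
never see them. Insertion codes are rejected (absent from the
structures in scope). Elements missing from the element column are
inferred from the atom name (digit-stripped first letter, which maps
hydrogen naming variants to H).

"Backbone" means N, CA, C, O. The carbonyl oxygen is included because
it is part of the standard backbone definition; an N/CA/C-only set is
available through `backbone_atoms=BACKBONE_ATOMS_NO_O` wherever a
selection is built, since published analyses do not always state which
convention they used. Cross-condition and ensemble-to-reference atom
matching is by (chain, residue number, atom name), so wild-type and
mutant systems align even when side-chain atom counts differ at the
mutated positions.

## Superposition and RMSD

`kabsch_fit` solves the orthogonal Procrustes problem by SVD with the
standard determinant correction, so reflections are never returned;
configurations with two vanishing singular values (collinear or
coincident points) raise, and near-planar fits are logged. Weights
default to uniform — nothing in the analyses reproduced here
mass-weights. RMSD series refit every frame to the reference
independently (the convention of trajectory tools for
"RMSD with respect to the crystal structure"), so any prior global
placement of the trajectory is irrelevant. The test suite checks the
closed-form solution against a brute-force Nelder–Mead search over the
rotation-vector parameterisation from many random starts; agreement is
at machine precision on small instances, far inside the 10⁻³ Å bound
asserted.

## Backbone PCA

Frames are superposed iteratively onto the evolving mean conformation
(reference-free) until the mean shifts by less than 10⁻⁶ Å RMS, then
superposed once more onto the converged mean. This final pass makes
every stored deviation exactly orthogonal to the six rigid-body modes
at the mean (the per-frame Kabsch optimality conditions are zero net
translation and zero rotational moment), which is why projecting
`mean + a·PC1` yields `(a, 0, …)` to machine precision rather than to
first order. The covariance of the pooled superposed coordinates is
diagonalised with a symmetric eigensolver; component signs are fixed
(largest-magnitude loading positive) so projections are reproducible
across runs.

One PCA is fitted over all supplied conditions pooled — required for a
shared PC1–PC2 subspace in which conditions can be compared —
with per-condition fitting available by passing a single ensemble.
Equilibration is expressed as an explicit per-ensemble frame window;
there is no automatic equilibration detection, mirroring the practice
of manually designating the stationary tail of a production run.
Density contours of 2-D projections use a Gaussian KDE with Scott
bandwidth (no bandwidth is dictated by the analyses reproduced here);
the iso-density threshold for a probability level q is the (1−q)
quantile of the sample-point densities, so the extracted contour
encloses at least ≈q of the sample.

## Contacts and dCNA

A contact exists in a frame when the minimum heavy-atom distance
between two residues is ≤ 4.5 Å; a distance exactly at the cutoff
counts (a fixed convention — published analyses rarely state the tie
rule). Same-chain pairs require |i−j| ≥ 3 in author numbering;
inter-chain pairs are always eligible, because a sequence-separation
rule across subunits would be meaningless. Candidate atom pairs come
from a k-d tree; the test suite asserts exact set equality with an
all-pairs scan over random frames. Contact probabilities are stored as
exact frame counts (rational arithmetic), so downstream sums carry no
floating-point drift.

`df = P(mutant) − P(reference)` is computed over the union of pairs
seen in either condition, with absent pairs contributing probability 0
— dropping contacts formed only in one condition would discard exactly
the signal of interest. The significance threshold defaults to 0.1,
the customary estimate of the statistical error of contact
probabilities from equilibrated trajectories; it is a parameter, and a
block-bootstrap per-pair error estimate can replace it where data-driven
thresholds are wanted.

Communities are detected on the reference (wild-type) probability map
by default: divisive Girvan–Newman clustering on the persistent-contact
graph (edges with P ≥ 0.5, probability weights; betweenness uses the
−log P edge length so persistent contacts are short), scanning the full
dendrogram and keeping the partition of maximum probability-weighted
modularity. Ties in edge betweenness are broken by removing the
lexicographically smallest (chain, resid) pair, making the procedure
deterministic; ties in modularity go to the coarsest partition. The
0.5 edge threshold selects a persistent-contact skeleton and is
configurable. Coarse-graining sums df exactly (rationals) over
community pairs, keeping intra-community changes as self-loops, so the
coarse total equals the residue-level total bit-for-bit.

## Assay statistics

Fold-increase is variant mean over wild-type mean; the specificity
ratio is cGMP mean over cAMP mean of the same variant. Both round
half-up to the printed precision (one decimal; the wild-type ratio is
printed at integer precision), because that is how the published cells
were produced from unrounded means. The cGMP fold-increase column of
the published table is *not* reproducible from its printed means (e.g.
12.2/1.9 = 6.4 against a printed 6.5 — the upstream computation used
unrounded means), and one specificity ratio (28.6/3.1 = 9.2 against a
printed 9.0) shares that defect; only cells that reproduce from printed
means are asserted. The t test recovers sd = SEM·√n and uses the pooled
(Student) variant by default, Welch optionally; replicate counts are
reported only as "three or more", so n defaults to 3 with a loud
warning and the resulting p-values are treated as approximate — they
are checked against a numerical-integration oracle of the t
distribution, not against published stars.

## Synthetic ground truth

The generators stand in for microsecond explicit-solvent MD of the
catalytic domain, which is out of scope (and not deposited); they
emulate the *statistical structure* the analyses consume, not the
physics.

* `make_toy_heterodimer` builds a two-chain helical polyalanine-like
  structure (N, CA, C, O, CB per residue) with bonded distances in the
  1.2–1.8 Å range and a small seeded jitter to break degeneracies.
* `generate_two_state` plants a collective displacement orthogonal to
  the rigid-body subspace of the base structure — otherwise
  superposition could absorb part of the planted motion and confound
  recovery tests. `separation` and `sigma` are both per-atom RMS
  displacements in Å (an RMSD-like scale): the state-B offset is
  `separation·√N·v` with ‖v‖=1, and the noise has per-coordinate sd
  `sigma/√3`. On this scale the planted mode dominates the spectrum —
  PC1 variance fraction ≈ w(1−w)·sep²/(w(1−w)·sep² + σ²) ≈ 0.96 at
  sep = 10σ, w = ½ — making "separation 10× noise" a meaningful
  recovery condition. A shared `base_seed` lets several conditions
  differ only in their state mixture while moving along one common mode.
* `generate_contact_flicker` realises independent Bernoulli contact
  streams geometrically: listed pairs toggle between 3.8 Å (contact)
  and 6.5 Å (no contact) — both far from the 4.5 Å cutoff so noise
  cannot flip a draw — on a 20 Å grid where nothing else ever touches.
  Each residue may appear in only one planted pair (its position would
  otherwise be over-constrained). `flicker_probability_maps` draws the
  identical Bernoulli substreams without building coordinates, for
  replicate studies; the test suite verifies the two routes produce
  identical counts.
* The assay fixture transcribes the published wild-type/mutant summary
  table (mean, SEM; n defaulted to 3) and is byte-reproducible.

Default study conditions: two-state ensembles of 2000 frames at
separation 3.0 Å = 10× sigma 0.3 Å and mixture weight 0.5; df recovery
uses 10 planted pairs at df = 0.25 (0.50 → 0.75) plus 20 null pairs at
P = 0.4 over 2000 frames per condition and 100 replicates; community
recovery uses three 8-residue blocks at P(within) = 0.9,
P(between) = 0.05. The analysis drivers use 600-frame ensembles per
condition, sized so the full sequence runs in seconds while every
qualitative conclusion is unchanged at larger n.

What passing these benchmarks shows: the estimators and algorithms are
correct against planted truth and exact oracles. What they do not
show: anything about force-field adequacy, sampling convergence of real
trajectories, or the magnitude of conformational change in the real
enzyme — those depend on MD inputs this package deliberately does not
produce.

## Known limitations

* PDB only (no mmCIF or binary trajectory formats); no insertion codes.
* Atom matching is strictly by chain/resid/atom-name — no sequence
  alignment fallback.
* Girvan–Newman is quadratic-ish in edges; community detection is meant
  for residue-level contact graphs (hundreds of nodes), not atom graphs.
* The replicate count of the assay table is not published per row;
  p-values derived with the defaulted n = 3 are indicative only.
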