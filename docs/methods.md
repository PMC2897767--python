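# Methods

This note records the models, parameter choices and numerical decisions
behind `capflex`, and what the synthetic benchmarks do and do not
demonstrate.

## Structure model

All analyses run on Cα-only models. Residues are identified by
(chain, author residue number, insertion code); author numbering is kept
exactly as deposited so results can be cited the way crystallographers
cite them (e.g. α-Arg266). Parsing (PDB and mmCIF) is delegated to
gemmi; HETATM records and waters are dropped, alternate locations
resolve to the highest-occupancy conformer (first in file order on a
tie), and multi-model files use the first model with a warning. Two
models are compared on the intersection of their residue keys — the
package never aligns sequences; if two files disagree about what residue
number a position carries, that is a data problem the user must resolve
with a selection or renumbering outside the package.

## Superposition

The optimal rigid superposition uses the Kabsch construction: SVD of the
cross-covariance of the centred point sets, with the smallest singular
direction's sign flipped when the naive solution would be a reflection.
The fit set and the measurement set are independent: `kabsch_fit` fits
on an optional selection and reports per-residue deviations over all
pairs, which is how one anchors on a rigid core and reads off how far
everything else moves. Degenerate inputs (fewer than three pairs, or a
collinear fit set) raise rather than return a silently arbitrary
rotation.

## Rigid-domain decomposition

No single canonical algorithm exists for splitting a conformational
change into rigid domains, so the package uses a deterministic,
transparent two-stage procedure:

1. **Seeding.** Average-linkage agglomerative clustering of residues
   with the difference distance matrix as dissimilarity, cut at k
   clusters. Coordinate noise can make the k-cut isolate one or two
   outlier residues as a "domain"; in that case the tree is cut deeper
   until k clusters of ≥ 3 residues exist, the k largest are kept, and
   stragglers join the kept cluster with the smallest mean
   dissimilarity.
2. **Refinement.** Each domain is superposed separately; every residue
   is reassigned to the domain whose fit leaves it the smallest
   deviation; repeat to convergence (≤ 50 iterations). Ties keep the
   current assignment, so the procedure is deterministic and cannot
   oscillate on exact ties.

Domains carry no sequence-contiguity constraint — the capping protein's
small domain is itself discontiguous in sequence. Domains are ordered by
decreasing size, so index 0 is always the large ("CP-L-like") domain.

## Screw decomposition

The residual transform of the moving domain (after superposing the two
conformations on the reference domain) is decomposed via its rotation
vector: θ = |rotvec|, axis n = rotvec/θ, parallel translation d = n·t,
and axis anchor from the least-norm solution of (I − R)p = t − d·n,
slid along the axis to the point nearest the moving domain's centroid
for reportability. Below θ = 0.1° the axis direction is numerically
meaningless and is reported as undefined (the angle is still returned).
The angle's sign is discarded (range [0°, 180°]); only the magnitude is
physically identified here. Reconstructing the transform from the screw
parameters reproduces the input to 1e-6, which the test suite checks on
random transforms.

## Elastic-network model

The network connects every Cα pair closer than a cutoff `R_c` with a
uniform harmonic spring (potential `E = (C/2) Σ (|r_ij| − |r⁰_ij|)²`),
giving the standard anisotropic-network Hessian: off-diagonal 3×3 block
`−C û ûᵀ` per edge, diagonal blocks minus the row sums. Defaults:

* `R_c` **= 12 Å** — a standard anisotropic-network choice; exposed as
  `--cutoff`. Axis directions are fairly insensitive to it as long as
  the network is connected.
* `C` **= 1** (arbitrary units). Eigenvalues scale linearly in C and
  eigenvectors are unchanged, so C has no effect on any reported
  geometry.
* **Zero-mode tolerance** — eigenvalues below 1e-8 × λ_max are flagged
  rigid; a connected network yields exactly six. A significantly
  negative eigenvalue raises, since it can only come from a broken
  Hessian.
* **Eigensolver** — dense symmetric (`scipy.linalg.eigh`). For the
  ~500-residue systems this package targets, 3N ≈ 1500 and the full
  spectrum takes seconds; no sparse machinery is warranted.

Displacements of a mode are the eigenvector scaled by 1/λ, making soft
modes large in the thermal-amplitude ordering. Because eigenvectors are
unit-normalised and C is arbitrary, the *absolute* scale of squared
displacements (Å²) is conventional. The extraction of rotation axes
therefore supports two thresholding modes: an absolute squared-
displacement threshold (default 2.0 Å², matching the convention of
anchoring on residues that "barely move", with 1.0 Å² the tighter
choice for ligand complexes), and a scale-free quantile mode (default:
the lowest 15% of residues) that is invariant to C and to system size.
The quantile mode is what the synthetic benchmarks use.

Collected low-displacement residues are grouped by single-linkage
spatial clustering at 8 Å (roughly two Cα shells), groups under 3
residues are discarded, and each group contributes the first principal
component of its member coordinates, anchored at the group centroid, as
an axis. Chain composition per group is reported, never assumed — on
the capping protein the groups segregate by subunit, but that is an
observation to check, not a constraint.

## Synthetic generator

The generators produce exactly the statistical structure the estimators
assume: two rigid bodies related by a known screw across two
conformations, with optional isotropic Gaussian coordinate noise added
independently to both conformations.

* Bodies are rejection-sampled Gaussian clouds with a hard minimum
  spacing of 3.6 Å (a Cα–Cα-like distance) and a width set by
  protein-like packing (~1 residue per 120 Å³); candidates beyond 1.5σ
  are rejected so the cloud has no sparse tail that would disconnect
  the elastic network at the default cutoff.
* The two bodies are stacked **along** the planted axis with a 4 Å seam,
  so the axis crosses the domain boundary and runs through both bodies —
  the geometry of the capping protein's inter-domain axis. The softest
  internal network mode of this assembly is the relative torsion of the
  bodies about the stacking axis (tangential sliding at the seam is far
  cheaper in spring energy than prying it open), which is what makes
  recovery of the planted axis through the mode-analysis path a
  meaningful, non-circular test.
* Reference conditions used by the test suite and the acceptance
  script: 150 + 100 residues, planted twist 10°, noise σ = 0.2 Å
  (matching the scale of coordinate uncertainty between independently
  refined crystal forms); the angle-recovery sweep spans 5°–45° at
  σ = 0.3 Å. All generators are pure functions of their parameters and
  seed.

**What passing these benchmarks shows — and what it does not.** The
blobs have protein-like density and two-chain topology but no backbone
connectivity, secondary structure, or anisotropic contact network.
Recovery of planted parameters demonstrates that the estimators are
correct and stable under coordinate noise; it does not demonstrate that
a particular real protein decomposes into two rigid domains — that
conclusion always comes from running the pipeline on the real
structures (the accession-gated tests do exactly that for the capping
protein when the deposited entries are available).

## Numerical details and edge cases

* RMSD is invariant (to 1e-8) under a common rigid motion of both
  conformations, symmetric in its arguments, and validated against two
  independent oracles: the Horn quaternion eigenvalue method and a
  refined random rotation search.
* The Hessian is validated entry-wise against central-difference second
  derivatives of the network energy (1e-5) and its spectrum against a
  second dense eigensolver (1e-8).
* Difference distance matrices are exactly zero for rigid motions,
  which serves as the null case for the decomposition (identical
  conformations short-circuit to a "no conformational change" report).
* Selections are inclusive on both ends, chain-scoped, in author
  numbering; selecting absent residues matches nothing and is logged,
  because crystal forms routinely differ in which residues are
  resolved. Pairing is by key intersection; the paired count is logged
  so RMSD denominators are auditable.
* PDB output clamps B-factor-column scores to the fixed-width field
  ([−99.99, 999.99]); coordinates round-trip at 3 decimals.

## Known limitations

* Pairing is strictly by residue key: no sequence alignment, so
  comparing non-identical constructs requires consistent author
  numbering.
* k > 2 hierarchical motion trees, torsion-based hinge detection,
  mass-weighted or Gaussian (isotropic) network variants, and B-factor
  calibration of the spring constant are out of scope.
* The screw angle is reported as a magnitude; handedness relative to a
  reference frame is available from the axis direction but is not
  assigned a sign convention.
* Deposited chain identifiers vary between PDB entries; the packaged
  capping-protein config assumes α = chain A, β = chain B and must be
  overridden when an entry labels its subunits differently.
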