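# Methods

This note documents the models and procedures mtlmorph implements, the
parameters that matter, what the phantom generator does and does not
emulate, and the design decisions taken where the protocol left choices
open.

## Normative z-score maps

Both feature maps compare a subject voxel-wise against a normal-control
database (NCDB): `z = (x - mean_N) / sd_N`. All volumes of a cohort must
share one grid (shape, spacing, space identifier); no resampling or
reorientation is performed — registration is upstream, and only the voxel
spacing (mm) enters any computation. The SD divisor is population (`n`) by
default with a `n-1` switch; population matches common z-map software and
makes the SD invariant under duplicating the cohort. Voxels with zero SD
are excluded from the z-map validity mask rather than producing
infinities; the stored z is 0 off-mask, but the mask is authoritative.

**GMV pipeline** (order fixed): global GMV normalization → 6 mm FWHM
Gaussian smoothing → z-scoring. Global normalization is proportional
scaling of each subject's map so its total GM volume (value sum × voxel
volume) equals the NCDB mean total; it removes inter-subject head-size
variance so that voxel-wise differences are local. The control SD image is
*not* smoothed: low-count voxels where smoothing would matter occur only
at the brain border, far from the MTL, and smoothing the SD would dilute
the contrast in small structures. Smoothing uses a separable Gaussian with
`sigma = fwhm / (2 sqrt(2 ln 2))` per axis, converted to voxel units via
spacing, with zero-padded borders (conventional VBM behavior).

**Thickness pipeline**: binarize the *unsmoothed* normalized GM map at 0.4
(inclusive: a voxel exactly at threshold is gray matter — the protocol does
not state strictness, so the tie case is fixed and tested) → 26-direction
run-length → z-scoring with a 3 mm-FWHM-smoothed control SD. Thickness z
is computed only on the subject's own GM mask: z-scores at voxels outside
a subject's gray matter would reflect tissue-boundary variance, not
thinning.

## Run-length cortical thickness

At each GM voxel, for each of the 13 antipodal direction pairs `d` of the
26-neighborhood, count the contiguous in-mask voxels reachable by integer
steps in `+d` (`n+`) and `-d` (`n-`), excluding the start; the pair length
is `(n+ + n- + 1) * step_mm(d)` with `step_mm(d) = sqrt(sum_i (d_i *
spacing_i)^2)`, and the run-length is the minimum over the 13 pairs.
Decisions fixed here:

* **Start voxel counted once** (`+1`): an axis-aligned slab k voxels thick
  reads exactly `k * spacing`, the natural "thickness" interpretation. The
  alternative (not counting the start) would make a 1-voxel structure read
  0 mm.
* **Border terminates the march** (treated as tissue boundary). Phantoms
  embed the cortex away from the border, so tests are unaffected; real
  cortices never touch the volume edge in registered space.
* **Anisotropic spacing** is supported through the physical step length;
  on the usual 1 mm isotropic grid the steps are 1, √2, √3 mm.
* Off-mask voxels get run-length 0; on-mask values are ≥ the smallest axis
  step by construction.

The vectorized implementation (fixed-point propagation of directional run
counts) is verified exactly against a naive per-voxel marching oracle on
random masks, and against analytic slab/shell phantoms.

## VOI and atrophy indicators

The VOI is `{t >= threshold}` of the voxel-wise pooled-variance two-sample
t statistic (NC mean − AD mean) on smoothed, normalized GM maps, after
removing 26-connected components smaller than a minimum cluster size. The
statistic and threshold were open choices; the pooled t is the standard
two-group VBM contrast. On real data `t ≈ 3` (p < 0.001) is conventional.
On phantoms the only variance source is small measurement noise, so t
plateaus in the tens inside true atrophy regions and a realistic threshold
acts as a near-zero cut that floods the mask with smoothing halo; the
phantom-study driver therefore defaults to `t >= 12`, a modest fraction of
the observed plateau. Phantom runs can bypass detection entirely with the
generator's exported ground-truth mask.

Indicators (whole-VOI and per atlas sub-region, all defined as 0 when no
voxel qualifies — "no detectable decline"):

* **GMV decline** = mean of negative GMV z in the VOI (≤ 0).
* **Thickness decline** = Σ z / run-length over VOI voxels with negative
  thickness z (≤ 0). Dividing by the subject's own run-length up-weights
  voxels where the cortex is already thin; a plain mean would understate
  mixed mild/severe atrophy. The divisor could also be read as the NCDB
  mean run-length; that variant is available as a configuration switch
  (`normalizer="ncdb_mean"`).
* **Extent** = fraction of valid VOI voxels with GMV z strictly below −2
  (strict inequality chosen and documented; the cut is a parameter).

Sub-regions come from intersecting the VOI with an integer label atlas
(AAL-style on real data; the phantom ships a synthetic 6-label atlas that
slices its two MTL blobs into three bands each). Empty intersections are
reported as such, never silently dropped.

## SVM prediction

Baseline indicators are z-transformed column-wise (population SD) over the
full sample and fed to an RBF-kernel soft-margin SVM. Accuracy is
leave-one-out cross-validation, maximized over a grid of `C ∈ 2^-5..2^15`,
`γ ∈ 2^-15..2^3` (powers of 2, step 2 in the exponent — the canonical
libsvm grid), ties broken by smallest C then smallest γ. Three-way
problems use one-vs-one voting with ties resolved by aggregate decision
values (the SVM's native multiclass scheme). Two deliberate fidelity
choices, both with leakage-free alternatives available:

* hyperparameters are selected by the *same* LOOCV that reports accuracy
  (optimistically biased; `nested=True` runs an inner LOOCV per fold);
* the z-transformation is fitted on the full sample
  (`pretransformed=False` on externally per-fold-standardized data avoids
  this).

Class weighting is off by default (groups are modestly unbalanced);
`class_weight="balanced"` is available.

## Longitudinal rates and statistics

Per-subject annual rates are ordinary least-squares slopes of indicator
versus visit time in years, requiring ≥ 3 visits and (by default) ≥ 1 year
of follow-up; shorter series produce noise-dominated slopes and are
excluded with a report.

Group comparisons are gatekept: a Kruskal–Wallis H omnibus (tie-corrected,
chi-square p, k−1 df; the all-identical degenerate case is reported as
H = 0, p = 1), and only if significant, pairwise two-sided Mann–Whitney U
tests with Holm–Bonferroni step-down correction. The Holm family is the
set of pairwise comparisons of one indicator (m = 3 for three groups);
pooling families across indicators is the caller's choice of input. The
Mann–Whitney p is exact (full enumeration of group assignments, mid-ranks,
twice the smaller inclusive tail) when the combined sample is ≤ 20 without
ties, and a tie-corrected normal approximation otherwise — without
continuity correction, which measurably overcorrects at the sample sizes
that reach the asymptotic path (empirical type-I error ≈ 0.049 vs ≈ 0.047
with it, at n = 30 + 30). Forcing `method="exact"` enumerates even with
ties. Spearman's r is the Pearson correlation of mid-ranks; its p is a
full permutation p for n ≤ 9 and the usual t approximation otherwise.

## The phantom generator

The generator emulates what the pipeline consumes — modulated GM
probability maps on a common grid — with known ground truth:

* **Geometry**: an axis-aligned slab or spherical shell cortex; analytic
  shapes are rasterized with 2×2×2 subvoxel sampling so edge voxels get
  fractional partial-volume values like real probabilistic maps.
* **MTL region**: two ellipsoidal blobs straddling the cortex; exported as
  the ground-truth VOI and sliced into the synthetic atlas.
* **Effects**: GM *amount* loss is a multiplicative factor on values inside
  the blobs; cortical *thinning* moves the cortex boundary inward in mm —
  geometric, not value-scaling, so the two indicators can be probed
  independently. Both decline linearly with visit time.
* **Anatomical variability**: a per-subject Gaussian jitter of the cortex
  outer boundary (SD 0.3 mm), fixed across a subject's visits. Without it
  every control would have identical run-lengths, the thickness SD would
  be identically zero, and thickness z-maps would be undefined.
* **Noise**: additive Gaussian on GM values (SD 0.05), redrawn per visit,
  clipped to [0, 1]. The nominal cortex GM value is 0.85, far enough from
  both clip bounds that clipping does not distort the noise.
* **Determinism**: per-subject seeds are a 31-bit slice of
  `sha256(f"{seed}|{subject_id}")`; identical spec + seed reproduces a
  cohort bit-for-bit.

Default study conditions (`run_phantom_study`): 64³ grid at 1 mm, shell
cortex 6 mm thick, blob radius 7 mm, group sizes 15 AD / 23 MCI / 26 NC /
25 NCDB, effects AD (GM factor 0.60, thinning 1.0 mm), MCI (0.80,
0.5 mm), NC/NCDB (1.0, 0 mm), annual decline rates graded the same way.
Reduced-scale runs shrink the geometry proportionally but keep cortex
thickness and effect sizes in absolute mm.

**What the phantom does not emulate**: real neuroanatomy (folding, partial
voluming of adjacent structures), registration error, scanner effects,
age/sex covariates, or realistic population variance structure. Passing
tests therefore demonstrate that the *algorithms* do what they claim
(exact formulas, oracle equivalence, recovery of injected effects and
their ordering), not that the method attains any particular clinical
accuracy: the phantom's group separations are many pooled SDs, so perfect
LOOCV accuracies on it say nothing about patient data.

## Numerical choices and degenerate inputs

* Gaussian smoothing: zero-padded borders; FWHM 0 is the identity.
* Zero-SD voxels: excluded via the validity mask (no minimum-SD floor for
  GMV; the thickness SD smoothing handles its zeros).
* Empty indicator sets: indicator = 0; an empty VOI ∩ validity
  intersection is an error.
* Degenerate statistics: all-identical Kruskal–Wallis input → (0, 1);
  constant correlation inputs and zero-variance feature columns are
  errors; t-map voxels with zero pooled variance are treated as t = 0.
* LOOCV grid ties: iterate the sorted grid, keep strict improvements only.

## Problem sizes used by the test suite

The acceptance checks run the full 64³ cohort once (shared fixture) and a
classifier-sensitivity sweep on 36³ cohorts of 8 + 8 subjects over 5 seeds
and 3 effect levels; oracle-equivalence checks use 50 random 20³ masks;
null calibrations use 2000 replicates per test. These sizes make the whole
suite a desk-scale run while keeping every check at full statistical
strength for the property it asserts.
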