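# mtlmorph

Morphometric MRI analysis of medial-temporal-lobe (MTL) atrophy: normative
z-score maps of gray-matter volume (GMV) and run-length cortical thickness,
VOI-based atrophy indicators, SVM group prediction, and longitudinal
atrophy-rate estimation — with a phantom generator that provides ground
truth for every stage.

## Who this is for

Researchers working with voxel-based morphometry of Alzheimer's disease
(AD), mild cognitive impairment (MCI) and normal aging who want a tested,
scriptable implementation of the z-score-map / atrophy-indicator protocol.
The package consumes **modulated, spatially registered gray-matter
probability volumes** (NIfTI); segmentation, DARTEL-style registration and
modulation are upstream and out of scope.

## The method

Given a normal-control database (NCDB) of `n` registered GM volumes, two
per-subject feature maps are z-scored voxel-wise against the controls:

```
Z(v) = (X(v) - mean_N(v)) / sd_N(v)
```

* **GMV** — each map is globally normalized (proportionally rescaled to the
  NCDB mean total GMV), smoothed with a 6 mm FWHM Gaussian, and z-scored.
  The control SD image is deliberately *not* smoothed.
* **Run-length cortical thickness** — the unsmoothed GM map is binarized at
  0.4; at every GM voxel, for each of the 13 antipodal direction pairs of
  the 26-neighborhood, the contiguous in-mask extent through the voxel is
  `(n+ + n- + 1) * step_mm`, and the thickness proxy is the minimum over
  the 13 pairs. The control SD image is smoothed at 3 mm FWHM before
  z-scoring (run-lengths of small structures can be identical across all
  controls), and z is defined only on the subject's own GM mask.

A volume of interest (VOI) is defined by a voxel-wise pooled-variance
t-comparison of AD vs NC GM maps (threshold + 26-connectivity cluster
cleanup). Within the VOI, three indicators summarize each subject-visit:

| indicator | definition |
|---|---|
| GMV decline | mean of the negative GMV z-scores |
| thickness decline | sum of negative thickness z / run-length at that voxel |
| extent | fraction of VOI voxels with GMV z < −2 |

Baseline indicators (whole-VOI, or per atlas sub-region) feed an RBF-kernel
SVM evaluated by leave-one-out cross-validation with a (C, γ) grid search;
per-subject annual rates come from ordinary least-squares slopes over
visits; group differences use Kruskal–Wallis gatekeeping with
Holm-corrected pairwise Mann–Whitney tests, and correlations use Spearman's
rank coefficient.

## Worked example

```python
import mtlmorph as m

study = m.run_phantom_study(
    seed=7, shape=(40, 40, 40),
    n_per_group={"AD": 5, "MCI": 5, "NC": 6, "NCDB": 8},
)
print(study.baseline().groupby("group")[
    ["gmv_voi", "thickness_voi", "extent_voi"]].mean().round(3))
```

prints (from `examples/02_voi_and_indicators.py`):

```
       gmv_voi  thickness_voi  extent_voi
group
AD     -13.066       -442.018       1.000
MCI     -7.490       -234.593       0.901
NC      -0.538        -34.401       0.004
```

The phantom cohort injects graded atrophy (GM loss and cortical thinning in
a designated MTL region, severity AD > MCI > NC), and all three indicators
recover that ordering: more negative decline values and a larger extent
mean more atrophy. The detected VOI overlaps the phantom's true MTL region
at Dice 0.64 on this reduced grid (≈ 0.8 at the full 64³ study scale).

The `examples/` directory has one short script per capability: z-maps,
VOI + indicators, SVM prediction, and longitudinal rates + statistics. A
thin CLI (`mtlmorph simulate | build-ncdb | zmap-gmv | zmap-thickness |
define-voi | indicators | predict | longitudinal | stats`) wraps the same
functions for file-based pipelines.

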