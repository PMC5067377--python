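"""Generate a phantom cohort and z-score one patient against its controls.

Builds a small normative database (10 controls), computes the GMV and
run-length thickness z-maps of one AD-like subject, and shows that both maps
are depressed inside the designated MTL region and flat elsewhere.
"""

import numpy as np

import mtlmorph as m
from mtlmorph import ncdb, phantom, thickness, zmap

spec = m.study_spec(seed=1, shape=(40, 40, 40))

controls = [
    phantom.make_subject(spec, "NCDB", 0.0, subj_seed=m.subject_seed(1, f"NCDB{i:03d}"))
    for i in range(10)
]
ref = zmap.reference_total_gmv(controls)
controls_norm = [zmap.global_gmv_normalize(v, ref) for v in controls]

gmv_model = ncdb.build_gmv_ncdb(
    [ncdb.gaussian_smooth(v, 6.0) for v in controls_norm], fwhm_mm=6.0
)
th_model = ncdb.build_thickness_ncdb(
    [thickness.run_length_map(thickness.binarize_gm(v)).values for v in controls_norm],
    sd_fwhm_mm=3.0,
)

subject = phantom.make_subject(spec, "AD", 0.0, subj_seed=m.subject_seed(1, "AD000"))
norm = zmap.global_gmv_normalize(subject, ref)
z_gmv = zmap.gmv_zmap(ncdb.gaussian_smooth(norm, 6.0), gmv_model, subject_id="AD000")
rl = thickness.run_length_map(thickness.binarize_gm(norm), subject_id="AD000")
z_th = thickness.thickness_zmap(rl, th_model)

truth = phantom.ground_truth_voi(spec).data.astype(bool)
for name, z in (("GMV", z_gmv), ("thickness", z_th)):
    valid = z.validity_mask.data.astype(bool)
    inside = z.z.data[truth & valid].mean()
    outside = z.z.data[~truth & valid].mean()
    print(f"{name:>9} z-map: mean z inside MTL {inside:7.2f}, outside {outside:7.2f}")

print(
    "\nNegative z inside the MTL region marks the injected atrophy (GM loss\n"
    "and cortical thinning); z near zero outside shows the normative model\n"
    "fits healthy tissue."
)
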