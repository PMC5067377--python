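"""Predict group membership from the atrophy indicators with an RBF SVM.

Leave-one-out cross-validation with a (C, gamma) grid search on the
baseline indicators of a reduced phantom cohort, for the two-way and
three-way problems.
"""

import numpy as np

import mtlmorph as m
from mtlmorph.predict import run_prediction_suite

study = m.run_phantom_study(
    seed=7,
    shape=(40, 40, 40),
    n_per_group={"AD": 6, "MCI": 6, "NC": 7, "NCDB": 8},
)

report = run_prediction_suite(
    study.baseline(),
    modes=("whole_voi",),
    feature_sets=("gmv", "thickness", "both"),
    C_grid=tuple(2.0 ** np.arange(-3, 10, 2)),
    gamma_grid=tuple(2.0 ** np.arange(-9, 2, 2)),
)

print("LOOCV accuracy (whole-VOI features):")
for key, res in report.items():
    _, fset, prob = key.split("/")
    print(f"  {prob:10s} {fset:9s}: {res['accuracy']:6.1%}  "
          f"(C=2^{int(np.log2(res['C']))}, gamma=2^{int(np.log2(res['gamma']))})")

print(
    "\nEach accuracy is the fraction of held-out subjects classified\n"
    "correctly by the SVM refit on the remaining ones, maximized over the\n"
    "hyperparameter grid. With the phantom's strong graded effects the\n"
    "combined feature set separates the groups essentially perfectly."
)
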