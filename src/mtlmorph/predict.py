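"""SVM group prediction from atrophy indicators.

Protocol: the per-subject baseline indicators (whole-VOI, or one value per
atlas sub-region) are z-transformed column-wise over the full sample, fed to
an RBF-kernel soft-margin SVM, and evaluated by leave-one-out cross-validation
(LOOCV) jointly with a grid search over (C, gamma).  The reported accuracy is
the maximum LOOCV accuracy over the grid, with ties broken by the smallest C
and then the smallest gamma.  Three-way problems use one-vs-one voting (the
SVM's native multiclass scheme), with voting ties resolved by the aggregate
decision values.

Selecting hyperparameters with the same LOOCV that reports accuracy is
optimistically biased; it is kept as the default for protocol fidelity, and a
nested variant (inner LOOCV on each training fold picks the
hyperparameters for that fold) is available.  Likewise the full-sample
z-transformation leaks the held-out subject's mean/SD; a leakage-free
per-fold option exists.
"""

from __future__ import annotations

import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

#: libsvm-style default search grid (powers of 2, step 2 in the exponent).
DEFAULT_C_GRID: tuple[float, ...] = tuple(2.0 ** np.arange(-5, 16, 2))
DEFAULT_GAMMA_GRID: tuple[float, ...] = tuple(2.0 ** np.arange(-15, 4, 2))

TWO_WAY_PROBLEMS = {
    "AD_vs_NC": ("AD", "NC"),
    "MCI_vs_NC": ("MCI", "NC"),
    "AD_vs_MCI": ("AD", "MCI"),
}
PROBLEMS = {**TWO_WAY_PROBLEMS, "three_way": ("AD", "MCI", "NC")}


def ztransform(features: pd.DataFrame) -> pd.DataFrame:
    """Column-wise standardization (x - mean) / SD, population SD.

    Fitted over all included subjects, as the prediction protocol specifies.
    Zero-variance columns are an error: they carry no information and make
    the transform undefined.
    """
    mean = features.mean(axis=0)
    sd = features.std(axis=0, ddof=0)
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero-variance feature column(s): {zero}")
    return (features - mean) / sd


def _loocv_predictions(X: np.ndarray, y: np.ndarray, C: float, gamma: float,
                       class_weight=None) -> np.ndarray:
    preds = np.empty(len(y), dtype=y.dtype)
    idx = np.arange(len(y))
    for i in idx:
        train = idx != i
        clf = SVC(C=C, gamma=gamma, kernel="rbf", class_weight=class_weight)
        clf.fit(X[train], y[train])
        preds[i] = clf.predict(X[i : i + 1])[0]
    return preds


def loocv_accuracy(
    features: pd.DataFrame,
    labels: Sequence[str],
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    class_weight=None,
    pretransformed: bool = False,
    nested: bool = False,
) -> dict:
    """LOOCV accuracy with grid search over (C, gamma).

    Returns a dict with the best accuracy, the chosen hyperparameters, the
    per-subject predictions under those hyperparameters, and the confusion
    matrix.  ``nested=True`` instead selects hyperparameters per fold by an
    inner LOOCV on the training subjects (leakage-free model selection).
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError(f"need >= 2 subjects per class, got {dict(zip(classes, counts))}")
    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("empty hyperparameter grid")
    Xdf = features if pretransformed else ztransform(features)
    X = np.asarray(Xdf, dtype=float)
    grid = list(itertools.product(sorted(C_grid), sorted(gamma_grid)))

    if nested:
        preds = np.empty(len(y), dtype=y.dtype)
        idx = np.arange(len(y))
        for i in idx:
            train = idx != i
            best = max(
                grid,
                key=lambda cg: (
                    np.mean(_loocv_predictions(X[train], y[train], *cg,
                                               class_weight=class_weight) == y[train]),
                    -cg[0], -cg[1],
                ),
            )
            clf = SVC(C=best[0], gamma=best[1], kernel="rbf", class_weight=class_weight)
            clf.fit(X[train], y[train])
            preds[i] = clf.predict(X[i : i + 1])[0]
        best_C = best_gamma = float("nan")
    else:
        best_acc, best_C, best_gamma, preds = -1.0, None, None, None
        for C, gamma in grid:
            p = _loocv_predictions(X, y, C, gamma, class_weight=class_weight)
            acc = float(np.mean(p == y))
            # strict improvement only: grid is sorted, so ties keep smallest C, gamma
            if acc > best_acc:
                best_acc, best_C, best_gamma, preds = acc, C, gamma, p

    accuracy = float(np.mean(preds == y))
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(preds, name="predicted"), dropna=False
    ).reindex(index=classes, columns=classes, fill_value=0)
    return {
        "accuracy": accuracy,
        "C": best_C,
        "gamma": best_gamma,
        "predictions": pd.Series(preds, index=features.index, name="predicted"),
        "confusion": confusion,
        "n": int(len(y)),
    }


def feature_columns(
    table: pd.DataFrame, mode: str, feature_set: str
) -> list[str]:
    """Select indicator columns for a (mode, feature_set) cell.

    Whole-VOI columns are ``gmv_voi`` / ``thickness_voi``; multi-region
    columns are ``gmv_r<label>`` / ``thickness_r<label>``.
    """
    if feature_set not in ("gmv", "thickness", "both"):
        raise ValueError(f"unknown feature_set {feature_set!r}")
    wanted = ("gmv", "thickness") if feature_set == "both" else (feature_set,)
    if mode == "whole_voi":
        cols = [f"{m}_voi" for m in wanted]
    elif mode == "multi_region":
        cols = [
            c
            for c in table.columns
            if any(c.startswith(f"{m}_r") for m in wanted)
        ]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"indicator table lacks columns: {missing}")
    return cols


def run_prediction_suite(
    indicator_table: pd.DataFrame,
    modes: Sequence[str] = ("whole_voi", "multi_region"),
    feature_sets: Sequence[str] = ("gmv", "thickness", "both"),
    problems: Sequence[str] = tuple(PROBLEMS),
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    class_weight=None,
) -> dict:
    """One LOOCV accuracy per (mode, feature_set, problem) cell.

    ``indicator_table`` holds one baseline row per subject with a ``group``
    column and indicator columns.  The report maps cell keys
    ``mode/feature_set/problem`` to the loocv_accuracy dict.
    """
    if "group" not in indicator_table.columns:
        raise ValueError("indicator table needs a 'group' column")
    report: dict[str, dict] = {}
    for mode in modes:
        for fset in feature_sets:
            cols = feature_columns(indicator_table, mode, fset)
            for prob in problems:
                groups = PROBLEMS[prob]
                sub = indicator_table[indicator_table["group"].isin(groups)]
                present = set(sub["group"])
                if present != set(groups):
                    raise ValueError(
                        f"problem {prob}: missing group(s) {set(groups) - present}"
                    )
                res = loocv_accuracy(
                    sub[cols], sub["group"].to_numpy(),
                    C_grid=C_grid, gamma_grid=gamma_grid,
                    class_weight=class_weight,
                )
                res["features"] = cols
                report[f"{mode}/{fset}/{prob}"] = res
    return report
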