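"""End-to-end phantom study: cohort -> normative models -> z-maps -> VOI ->
indicators.

This is the orchestration layer the acceptance checks, examples and CLI share.
It reproduces the analysis protocol on synthetic cohorts with known ground
truth: an NCDB of controls defines the normative models; every analysis
subject gets a GMV z-map (normalize -> smooth -> z) and a thickness z-map
(binarize -> 26-direction run-length -> z); the VOI comes from the AD-vs-NC
group comparison (or the phantom's exported truth mask); and each
subject-visit yields whole-VOI and per-subregion atrophy indicators.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ncdb as ncdb_mod
from . import phantom as ph
from . import thickness as th
from . import voi as voi_mod
from . import zmap as zm
from .io import VolumeGrid

#: Group sizes of the study cohort the phantom emulates.
DEFAULT_N_PER_GROUP = {"AD": 15, "MCI": 23, "NC": 26, "NCDB": 25}


def study_spec(
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 64, 64),
    group_effects: Mapping[str, ph.GroupEffect] | None = None,
    **overrides,
) -> ph.PhantomSpec:
    """The default phantom study conditions, scaled to the grid size.

    A spherical cortical shell 6 mm thick with two MTL blobs on the
    left/right mid-shell; atrophy severity graded AD > MCI > NC.  Geometry
    scales with the grid so reduced-size studies stay proportionate, while
    cortex thickness and effect magnitudes stay in absolute mm.
    """
    s = min(shape) / 64.0
    center = tuple(dim / 2.0 for dim in shape)
    outer = 24.0 * s
    cortex = ph.ShellCortex(center_mm=center, inner_radius_mm=outer - 6.0,
                            outer_radius_mm=outer)
    mid = (outer + cortex.inner_radius_mm) / 2.0
    r_blob = max(7.0 * s, 4.0)
    blobs = (
        ph.Blob((center[0] - mid, center[1], center[2]), (r_blob,) * 3),
        ph.Blob((center[0] + mid, center[1], center[2]), (r_blob,) * 3),
    )
    kwargs = dict(shape=shape, cortex=cortex, mtl_blobs=blobs, seed=seed)
    if group_effects is not None:
        kwargs["group_effects"] = dict(group_effects)
    kwargs.update(overrides)
    return ph.PhantomSpec(**kwargs)


@dataclasses.dataclass
class PhantomStudy:
    spec: ph.PhantomSpec
    indicators: pd.DataFrame  # one row per subject-visit
    voi: voi_mod.VOIMask
    truth_voi: VolumeGrid
    voi_dice: float
    gmv_model: ncdb_mod.NormativeModel
    thickness_model: ncdb_mod.NormativeModel
    atlas: VolumeGrid
    region_labels: tuple[int, ...]

    def baseline(self) -> pd.DataFrame:
        return self.indicators[self.indicators["visit_time_years"] == 0.0].copy()


def run_phantom_study(
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 64, 64),
    n_per_group: Mapping[str, int] | None = None,
    visits: Sequence[float] = (0.0,),
    spec: ph.PhantomSpec | None = None,
    voi_source: str = "group_comparison",
    fwhm_gmv_mm: float = 6.0,
    sd_fwhm_thickness_mm: float = 3.0,
    gm_threshold: float = 0.4,
    stat_threshold: float = 12.0,
    min_cluster_voxels: int = 30,
) -> PhantomStudy:
    """Run the whole cross-sectional pipeline on a seeded phantom cohort.

    The default ``stat_threshold`` of 12 differs from the t ~ 3 convention
    used on real data: the phantom's only variance source is small
    measurement noise, so group-difference t values inside true atrophy
    regions reach the tens and a realistic cut would act as a near-zero
    threshold, flooding the VOI with smoothing halo.
    """
    if spec is None:
        spec = study_spec(seed=seed, shape=shape)
    n_per_group = dict(n_per_group or DEFAULT_N_PER_GROUP)
    rows = ph.cohort_rows(spec, n_per_group, visits)

    # --- normative models from the NCDB controls -------------------------
    ncdb_rows = [r for r in rows if r["group"] == "NCDB"]
    subj_rows = [r for r in rows if r["group"] != "NCDB"]
    ncdb_raw = [
        ph.make_subject(spec, "NCDB", r["visit_time_years"], subj_seed=r["seed"])
        for r in ncdb_rows
    ]
    ref_total = zm.reference_total_gmv(ncdb_raw)
    ncdb_norm = [zm.global_gmv_normalize(v, ref_total) for v in ncdb_raw]
    ncdb_smoothed = [ncdb_mod.gaussian_smooth(v, fwhm_gmv_mm) for v in ncdb_norm]
    gmv_model = ncdb_mod.build_gmv_ncdb(ncdb_smoothed, fwhm_mm=fwhm_gmv_mm)
    ncdb_runlength = [
        th.run_length_map(th.binarize_gm(v, gm_threshold)).values for v in ncdb_norm
    ]
    thickness_model = ncdb_mod.build_thickness_ncdb(
        ncdb_runlength, sd_fwhm_mm=sd_fwhm_thickness_mm
    )
    del ncdb_raw, ncdb_norm, ncdb_smoothed, ncdb_runlength

    # --- per-subject z-maps ----------------------------------------------
    per_row = []
    baseline_smoothed: dict[str, list[VolumeGrid]] = {"AD": [], "NC": []}
    for r in subj_rows:
        vol = ph.make_subject(
            spec, r["group"], r["visit_time_years"], subj_seed=r["seed"]
        )
        norm = zm.global_gmv_normalize(vol, ref_total)
        smoothed = ncdb_mod.gaussian_smooth(norm, fwhm_gmv_mm)
        if r["visit_time_years"] == 0.0 and r["group"] in baseline_smoothed:
            baseline_smoothed[r["group"]].append(smoothed)
        z_gmv = zm.gmv_zmap(
            smoothed, gmv_model,
            subject_id=r["subject_id"], visit_time=r["visit_time_years"],
        )
        rl = th.run_length_map(
            th.binarize_gm(norm, gm_threshold), subject_id=r["subject_id"]
        )
        z_th = th.thickness_zmap(rl, thickness_model)
        per_row.append((r, z_gmv, z_th, rl))

    # --- VOI and sub-regions ----------------------------------------------
    truth = ph.ground_truth_voi(spec)
    if voi_source == "ground_truth":
        voi = voi_mod.VOIMask(mask=truth, provenance={"method": "ground_truth"})
    elif voi_source == "group_comparison":
        voi = voi_mod.define_voi(
            baseline_smoothed["AD"], baseline_smoothed["NC"],
            stat_threshold=stat_threshold, min_cluster_voxels=min_cluster_voxels,
        )
    else:
        raise ValueError(f"unknown voi_source {voi_source!r}")
    dice = voi_mod.dice(voi.mask, truth)
    del baseline_smoothed

    atlas = ph.make_atlas(spec)
    labels = tuple(int(v) for v in np.unique(atlas.data) if v != 0)
    subvois = voi_mod.split_by_atlas(voi, atlas, labels)

    # --- indicators --------------------------------------------------------
    records = []
    for r, z_gmv, z_th, rl in per_row:
        rec = {
            "subject_id": r["subject_id"],
            "group": r["group"],
            "visit_time_years": r["visit_time_years"],
            "gmv_voi": voi_mod.gmv_decline_indicator(z_gmv, voi),
            "thickness_voi": voi_mod.thickness_decline_indicator(z_th, rl, voi),
            "extent_voi": voi_mod.extent_indicator(z_gmv, voi),
        }
        for label in labels:
            sub = subvois[label]
            if sub is None:
                rec[f"gmv_r{label}"] = 0.0
                rec[f"thickness_r{label}"] = 0.0
                continue
            rec[f"gmv_r{label}"] = voi_mod.gmv_decline_indicator(z_gmv, sub)
            rec[f"thickness_r{label}"] = voi_mod.thickness_decline_indicator(
                z_th, rl, sub
            )
        records.append(rec)

    return PhantomStudy(
        spec=spec,
        indicators=pd.DataFrame(records),
        voi=voi,
        truth_voi=truth,
        voi_dice=dice,
        gmv_model=gmv_model,
        thickness_model=thickness_model,
        atlas=atlas,
        region_labels=labels,
    )
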