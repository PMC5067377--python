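"""Synthetic gray-matter phantoms with known ground truth.

The generator emulates what the analysis pipeline consumes: modulated,
spatially registered gray-matter probability volumes.  A phantom cortex is an
analytic slab or spherical shell of controllable thickness, rasterized with
subvoxel sampling so edge voxels receive fractional (partial-volume) values,
mimicking probabilistic GM maps rather than binary masks.

Disease effects are injected inside a designated "MTL" region (two ellipsoidal
blobs straddling the cortex):

* gray-matter *amount* loss — a multiplicative factor on GM values (0 < f <= 1);
* cortical *thinning* — the cortex boundary is moved inward geometrically, in
  mm, so volume and thickness effects are independently controllable;
* longitudinal decline — both effects worsen linearly with visit time;
* per-subject anatomy — a Gaussian jitter of the cortex outer boundary, fixed
  per subject across visits, so controls differ from one another the way a
  normative database requires (without it the run-length SD would vanish);
* measurement noise — additive Gaussian noise on GM values, clipped to [0, 1],
  redrawn per visit.

Controls (NC / NCDB) carry factor 1 and zero thinning: they are the reference
the z-scores are measured against.  Everything is seeded and bit-reproducible:
per-subject seeds derive from sha256(f"{seed}|{subject_id}").
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import VolumeGrid, save_volume, write_subjects_table


@dataclasses.dataclass
class SlabCortex:
    """Axis-aligned cortical slab: GM where start <= x_axis < start + thickness."""

    axis: int = 2
    start_mm: float = 10.0
    thickness_mm: float = 5.0


@dataclasses.dataclass
class ShellCortex:
    """Spherical cortical shell: GM where inner <= |p - center| <= outer."""

    center_mm: tuple[float, float, float] = (32.0, 32.0, 32.0)
    inner_radius_mm: float = 18.0
    outer_radius_mm: float = 24.0

    @property
    def thickness_mm(self) -> float:
        return self.outer_radius_mm - self.inner_radius_mm


@dataclasses.dataclass
class Blob:
    """Ellipsoidal region: |(p - center)/radii| <= 1."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d = (pts - np.asarray(self.center_mm)) / np.asarray(self.radii_mm)
        return (d * d).sum(axis=-1) <= 1.0


@dataclasses.dataclass
class GroupEffect:
    """Atrophy applied inside the MTL region for one group.

    gmv_factor multiplies GM values; thinning_mm moves the cortex outer
    boundary inward; the *_per_year rates are linear longitudinal declines.
    """

    gmv_factor: float = 1.0
    thinning_mm: float = 0.0
    gmv_rate_per_year: float = 0.0
    thinning_rate_mm_per_year: float = 0.0


@dataclasses.dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    cortex: SlabCortex | ShellCortex = dataclasses.field(default_factory=ShellCortex)
    mtl_blobs: Sequence[Blob] = dataclasses.field(
        default_factory=lambda: (
            Blob((11.0, 32.0, 32.0), (7.0, 7.0, 7.0)),
            Blob((53.0, 32.0, 32.0), (7.0, 7.0, 7.0)),
        )
    )
    group_effects: Mapping[str, GroupEffect] = dataclasses.field(
        default_factory=lambda: {
            "AD": GroupEffect(0.60, 1.0, 0.040, 0.10),
            "MCI": GroupEffect(0.80, 0.5, 0.020, 0.05),
            "NC": GroupEffect(1.0, 0.0, 0.010, 0.02),
            "NCDB": GroupEffect(1.0, 0.0, 0.0, 0.0),
        }
    )
    gm_value: float = 0.85
    noise_sd: float = 0.05
    thickness_jitter_sd_mm: float = 0.3
    seed: int = 0
    space_id: str = "phantom"

    def __post_init__(self) -> None:
        for name in ("NC", "NCDB"):
            eff = self.group_effects.get(name)
            if eff is not None and (eff.gmv_factor != 1.0 or eff.thinning_mm != 0.0):
                raise ValueError(f"{name} baseline must be the unatrophied reference")
        for name, eff in self.group_effects.items():
            if not (0.0 < eff.gmv_factor <= 1.0):
                raise ValueError(f"{name}: gmv_factor must lie in (0, 1]")


def subject_seed(master_seed: int, subject_id: str) -> int:
    """Deterministic per-subject seed: 31-bit slice of sha256(f"{seed}|{id}")."""
    digest = hashlib.sha256(f"{master_seed}|{subject_id}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _sample_points(shape, spacing):
    """2x2x2 subvoxel sample points per voxel -> array (..., 8, 3) in mm.

    Voxel i spans [i, i+1) voxel units; samples sit at offsets 0.25 / 0.75.
    """
    idx = np.indices(shape, dtype=np.float64)  # (3, X, Y, Z)
    base = np.stack([idx[a] * spacing[a] for a in range(3)], axis=-1)  # (X,Y,Z,3)
    offs = np.array(
        [[(ox + 0.5) / 2 * spacing[0], (oy + 0.5) / 2 * spacing[1], (oz + 0.5) / 2 * spacing[2]]
         for ox in (0, 1) for oy in (0, 1) for oz in (0, 1)]
    )  # (8, 3)
    return base[..., None, :] + offs  # (X, Y, Z, 8, 3)


def _in_blobs(pts: np.ndarray, blobs: Sequence[Blob]) -> np.ndarray:
    inside = np.zeros(pts.shape[:-1], dtype=bool)
    for b in blobs:
        inside |= b.contains(pts)
    return inside


def _rasterize(spec: PhantomSpec, factor: float, thin_mm: float, jitter_mm: float) -> np.ndarray:
    """Noise-free GM field: partial-volume fractions times gm_value times factor."""
    cortex = spec.cortex
    if thin_mm < 0:
        raise ValueError("negative thinning")
    eff_thickness = cortex.thickness_mm + jitter_mm
    if thin_mm >= eff_thickness:
        raise ValueError(
            f"requested thinning {thin_mm:.2f} mm exceeds cortex thickness "
            f"{eff_thickness:.2f} mm"
        )
    pts = _sample_points(spec.shape, spec.spacing)  # (X,Y,Z,8,3)
    in_mtl = _in_blobs(pts, spec.mtl_blobs)
    delta = np.where(in_mtl, thin_mm, 0.0)
    if isinstance(cortex, ShellCortex):
        r = np.linalg.norm(pts - np.asarray(cortex.center_mm), axis=-1)
        in_cortex = (r >= cortex.inner_radius_mm) & (
            r <= cortex.outer_radius_mm + jitter_mm - delta
        )
    else:
        x = pts[..., cortex.axis]
        in_cortex = (x >= cortex.start_mm) & (
            x < cortex.start_mm + cortex.thickness_mm + jitter_mm - delta
        )
    value = np.where(in_cortex & in_mtl, factor, 1.0) * in_cortex
    return spec.gm_value * value.mean(axis=-1)


def make_subject(
    spec: PhantomSpec,
    group: str,
    visit_time: float = 0.0,
    subj_seed: int | None = None,
    subject_id: str | None = None,
) -> VolumeGrid:
    """Generate one subject visit as a modulated GM volume.

    The per-subject anatomy jitter is drawn once from ``subj_seed`` (identical
    across visits); voxel noise is redrawn per visit.  Effects at visit time t:
    GM factor = max(gmv_factor - gmv_rate * t, 0), thinning = thinning_mm +
    thinning_rate * t, applied inside the MTL blobs only.
    """
    if group not in spec.group_effects:
        raise KeyError(f"no group effect defined for {group!r}")
    if subj_seed is None:
        subj_seed = subject_seed(spec.seed, subject_id or group)
    eff = spec.group_effects[group]
    rng_subject = np.random.default_rng(subj_seed)
    jitter = float(rng_subject.normal(0.0, spec.thickness_jitter_sd_mm))
    factor = max(eff.gmv_factor - eff.gmv_rate_per_year * visit_time, 0.0)
    thin = eff.thinning_mm + eff.thinning_rate_mm_per_year * visit_time
    data = _rasterize(spec, factor, thin, jitter)
    if spec.noise_sd > 0:
        rng_visit = np.random.default_rng([subj_seed, int(round(visit_time * 1000)) + 7])
        data = data + rng_visit.normal(0.0, spec.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, 1.0)
    return VolumeGrid(data, spec.spacing, spec.space_id)


def ground_truth_voi(spec: PhantomSpec) -> VolumeGrid:
    """The designated MTL region: voxels whose center lies inside the blobs.

    This is the region group effects are injected into, exported so detected
    VOIs can be validated against it.
    """
    idx = np.indices(spec.shape, dtype=np.float64)
    centers = np.stack([(idx[a] + 0.5) * spec.spacing[a] for a in range(3)], axis=-1)
    in_mtl = _in_blobs(centers, spec.mtl_blobs)
    return VolumeGrid(in_mtl.astype(np.uint8), spec.spacing, spec.space_id)


def make_atlas(spec: PhantomSpec, slices_per_blob: int = 3) -> VolumeGrid:
    """Synthetic integer-label parcellation: each MTL blob is cut into
    ``slices_per_blob`` slabs along z, giving 2 * slices_per_blob labels (1..6
    by default) — a stand-in for the handful of AAL regions the VOI covers."""
    idx = np.indices(spec.shape, dtype=np.float64)
    centers = np.stack(
        [(idx[a] + 0.5) * spec.spacing[a] for a in range(3)], axis=-1
    )
    labels = np.zeros(spec.shape, dtype=np.int32)
    next_label = 1
    for blob in spec.mtl_blobs:
        inside = blob.contains(centers)
        z = centers[..., 2]
        lo = blob.center_mm[2] - blob.radii_mm[2]
        width = 2.0 * blob.radii_mm[2] / slices_per_blob
        for k in range(slices_per_blob):
            band = inside & (z >= lo + k * width) & (z < lo + (k + 1) * width + 1e-9)
            labels[band] = next_label
            next_label += 1
    return VolumeGrid(labels, spec.spacing, spec.space_id)


def cohort_rows(
    spec: PhantomSpec,
    n_per_group: Mapping[str, int],
    visits: Sequence[float],
) -> list[dict]:
    """Deterministic subject/visit bookkeeping for a cohort.

    NCDB subjects contribute only a baseline visit (they define the normative
    model); all other groups get every requested visit.
    """
    rows = []
    for group, n in n_per_group.items():
        if n < 1:
            raise ValueError(f"n_per_group[{group!r}] must be >= 1")
        group_visits = [0.0] if group == "NCDB" else list(visits)
        for i in range(n):
            sid = f"{group}{i:03d}"
            for t in group_visits:
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "visit_time_years": float(t),
                        "seed": subject_seed(spec.seed, sid),
                    }
                )
    return rows


def make_cohort(
    spec: PhantomSpec,
    n_per_group: Mapping[str, int],
    visits: Sequence[float],
    out_dir: str | Path,
) -> pd.DataFrame:
    """Write a full phantom cohort to disk.

    Produces one NIfTI per subject-visit, a subjects TSV, the ground-truth VOI
    mask (truth_voi.nii.gz) and the synthetic atlas (atlas.nii.gz).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = cohort_rows(spec, n_per_group, visits)
    for row in rows:
        vol = make_subject(
            spec, row["group"], row["visit_time_years"], subj_seed=row["seed"]
        )
        fname = f"{row['subject_id']}_t{row['visit_time_years']:.2f}.nii.gz"
        save_volume(vol, out_dir / fname)
        row["gmv_path"] = fname
    table = pd.DataFrame(rows)[["subject_id", "group", "visit_time_years", "gmv_path"]]
    write_subjects_table(table, out_dir / "subjects.tsv")
    save_volume(ground_truth_voi(spec), out_dir / "truth_voi.nii.gz")
    save_volume(make_atlas(spec), out_dir / "atlas.nii.gz")
    return table
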