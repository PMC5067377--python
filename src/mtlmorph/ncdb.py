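"""Normative-control database (NCDB): voxel-wise mean/SD normative models.

A normative model is the voxel-wise mean and standard deviation over a cohort
of normal controls, one model per modality:

* ``gmv`` — built from globally normalized, smoothed GM volumes; the SD image
  is deliberately left unsmoothed (low-count voxels exist only at the brain
  border, far from the medial temporal VOI, and smoothing the SD would blur
  the contrast the z-maps are meant to measure);
* ``thickness`` — built from run-length maps; here the SD *is* smoothed
  (3 mm FWHM by default) because the run-length of small structures can be
  identical across all controls, which would make z-scores blow up.

Both smoothing choices are defaults, not hard-coded.  The SD divisor (n vs
n-1) is a configuration switch; population (n) is the default, matching usual
z-map software.  Voxels with SD = 0 are excluded from z-map validity masks
downstream rather than producing infinities.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import VolumeGrid, assert_cohort_compatible, load_volume, save_volume

#: FWHM of a Gaussian = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_smooth(img: VolumeGrid, fwhm_mm: float) -> VolumeGrid:
    """Separable Gaussian smoothing with FWHM given in mm.

    Sigma per axis is converted to voxel units via the grid spacing; the
    border is zero-padded (conventional VBM behavior).  fwhm 0 is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError(f"fwhm_mm must be >= 0, got {fwhm_mm}")
    if fwhm_mm == 0:
        return img.like(img.data.copy())
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / s for s in img.spacing]
    return img.like(ndimage.gaussian_filter(img.data, sigma_vox, mode="constant"))


@dataclasses.dataclass
class NormativeModel:
    """Voxel-wise mean/SD of a control cohort for one modality."""

    modality: str  # "gmv" | "thickness"
    mean_img: VolumeGrid
    sd_img: VolumeGrid
    n_controls: int
    sd_smoothing_fwhm_mm: float = 0.0
    input_smoothing_fwhm_mm: float = 0.0
    sd_divisor: str = "n"

    def __post_init__(self) -> None:
        if self.modality not in ("gmv", "thickness"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.n_controls < 2:
            raise ValueError("a normative model needs at least 2 controls")
        if np.any(self.sd_img.data < 0):
            raise ValueError("SD image must be non-negative")
        if not self.mean_img.compatible(self.sd_img):
            raise ValueError("mean and SD images must share one grid")


def _mean_sd(volumes: Sequence[VolumeGrid], sd_divisor: str):
    assert_cohort_compatible(volumes)
    if len(volumes) < 2:
        raise ValueError(f"need >= 2 controls, got {len(volumes)}")
    if sd_divisor not in ("n", "n-1"):
        raise ValueError(f"sd_divisor must be 'n' or 'n-1', got {sd_divisor!r}")
    stack = np.stack([v.data for v in volumes])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=0 if sd_divisor == "n" else 1)
    return volumes[0].like(mean), volumes[0].like(sd)


def build_gmv_ncdb(
    control_volumes: Sequence[VolumeGrid],
    fwhm_mm: float = 6.0,
    sd_divisor: str = "n",
) -> NormativeModel:
    """GMV normative model from already normalized+smoothed control volumes.

    ``fwhm_mm`` records the smoothing the inputs carry (subjects must be
    smoothed identically before z-scoring); the SD image itself is not
    smoothed.
    """
    mean, sd = _mean_sd(control_volumes, sd_divisor)
    return NormativeModel(
        modality="gmv",
        mean_img=mean,
        sd_img=sd,
        n_controls=len(control_volumes),
        sd_smoothing_fwhm_mm=0.0,
        input_smoothing_fwhm_mm=float(fwhm_mm),
        sd_divisor=sd_divisor,
    )


def build_thickness_ncdb(
    control_runlength_maps: Sequence[VolumeGrid],
    sd_fwhm_mm: float = 3.0,
    sd_divisor: str = "n",
) -> NormativeModel:
    """Thickness normative model from control run-length maps.

    The SD image is smoothed with a Gaussian of ``sd_fwhm_mm`` before storage
    so that voxels where every control happens to have an identical
    run-length do not produce unbounded z-scores.
    """
    mean, sd = _mean_sd(control_runlength_maps, sd_divisor)
    sd = gaussian_smooth(sd, sd_fwhm_mm)
    # smoothing a non-negative field keeps it non-negative up to rounding
    sd = sd.like(np.maximum(sd.data, 0.0))
    return NormativeModel(
        modality="thickness",
        mean_img=mean,
        sd_img=sd,
        n_controls=len(control_runlength_maps),
        sd_smoothing_fwhm_mm=float(sd_fwhm_mm),
        sd_divisor=sd_divisor,
    )


def save_model(model: NormativeModel, out_dir: str | Path) -> Path:
    """Persist a model as mean/sd NIfTI volumes plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_volume(model.mean_img, out_dir / "mean.nii.gz")
    save_volume(model.sd_img, out_dir / "sd.nii.gz")
    sidecar = {
        "modality": model.modality,
        "n_controls": model.n_controls,
        "sd_smoothing_fwhm_mm": model.sd_smoothing_fwhm_mm,
        "input_smoothing_fwhm_mm": model.input_smoothing_fwhm_mm,
        "sd_divisor": model.sd_divisor,
    }
    (out_dir / "model.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir


def load_model(model_dir: str | Path) -> NormativeModel:
    model_dir = Path(model_dir)
    sidecar = json.loads((model_dir / "model.json").read_text())
    return NormativeModel(
        mean_img=load_volume(model_dir / "mean.nii.gz"),
        sd_img=load_volume(model_dir / "sd.nii.gz"),
        **sidecar,
    )
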