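"""GMV z-score maps.

The gray-matter-volume pipeline is: global GMV normalization (proportional
scaling of each subject's map so its total GM volume matches the control
reference) -> Gaussian smoothing (6 mm FWHM by default, identical for
controls and subjects) -> voxel-wise z-scoring against the normative model,

    z = (X - mean_NC) / sd_NC,

defined wherever the control SD is positive.  Negative z marks gray-matter
loss relative to the normal-control database.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .io import VolumeGrid
from .ncdb import NormativeModel


@dataclasses.dataclass
class ZScoreMap:
    """Per-subject z-score volume for one modality.

    z is finite on the validity mask and stored as 0 elsewhere; the mask is
    authoritative — consumers must never interpret off-mask zeros as data.
    """

    z: VolumeGrid
    validity_mask: VolumeGrid
    modality: str  # "gmv" | "thickness"
    subject_id: str | None = None
    visit_time: float = 0.0

    def __post_init__(self) -> None:
        if self.modality not in ("gmv", "thickness"):
            raise ValueError(f"unknown modality {self.modality!r}")
        valid = self.validity_mask.data.astype(bool)
        if not np.all(np.isfinite(self.z.data[valid])):
            raise ValueError("non-finite z inside the validity mask")


def total_gmv(gmv: VolumeGrid) -> float:
    """Total gray-matter volume: value sum times voxel volume (mm^3-scaled)."""
    return float(gmv.data.sum() * gmv.voxel_volume_mm3)


def reference_total_gmv(control_volumes: Sequence[VolumeGrid]) -> float:
    """Mean total GMV over the control cohort; the normalization target."""
    return float(np.mean([total_gmv(v) for v in control_volumes]))


def global_gmv_normalize(gmv: VolumeGrid, reference_total: float) -> VolumeGrid:
    """Proportionally rescale a GM map so its total equals the reference.

    Corrects inter-subject variation in total brain volume so voxel-wise
    comparisons measure local, not global, differences.
    """
    if reference_total <= 0:
        raise ValueError("reference_total must be positive")
    tot = total_gmv(gmv)
    if tot <= 0:
        raise ValueError("subject has zero total GMV; cannot normalize")
    return gmv.like(gmv.data * (reference_total / tot))


def gmv_zmap(
    subject_gmv_smoothed: VolumeGrid,
    model: NormativeModel,
    subject_id: str | None = None,
    visit_time: float = 0.0,
) -> ZScoreMap:
    """Voxel-wise z-score of a (normalized, smoothed) subject GM map.

    The subject must have been normalized and smoothed exactly as the
    controls that built the model.  Validity mask = {SD > 0}.
    """
    if model.modality != "gmv":
        raise ValueError(f"expected a gmv model, got {model.modality!r}")
    if not subject_gmv_smoothed.compatible(model.mean_img):
        raise ValueError("subject grid incompatible with the normative model")
    sd = model.sd_img.data
    valid = sd > 0
    z = np.zeros(subject_gmv_smoothed.shape)
    z[valid] = (subject_gmv_smoothed.data[valid] - model.mean_img.data[valid]) / sd[valid]
    return ZScoreMap(
        z=subject_gmv_smoothed.like(z),
        validity_mask=subject_gmv_smoothed.like(valid.astype(np.uint8)),
        modality="gmv",
        subject_id=subject_id,
        visit_time=visit_time,
    )
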