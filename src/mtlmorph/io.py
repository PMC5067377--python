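"""Volume and cohort-table I/O.

Every downstream computation in this package is voxel-wise across subjects,
so all volumes of a cohort must live on one shared grid (same shape, voxel
spacing and named space).  This module owns that contract: :class:`VolumeGrid`
carries the grid metadata, and :func:`assert_cohort_compatible` enforces it
before any cross-subject arithmetic.

Volumes are exchanged as NIfTI (via nibabel); cohort bookkeeping is a TSV
read into a pandas DataFrame.  Spatial preprocessing (segmentation,
registration, modulation) happens upstream — volumes are used in array index
space and only the voxel spacing enters computation.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

GROUPS = ("AD", "MCI", "NC", "NCDB")

SUBJECTS_COLUMNS = ("subject_id", "group", "visit_time_years", "gmv_path")


@dataclasses.dataclass
class VolumeGrid:
    """A 3D scalar field on a named grid.

    Parameters
    ----------
    data:
        3D array (gray-matter amount, run-length in mm, z-scores, ...).
    spacing:
        Per-axis voxel size in mm, strictly positive.
    space_id:
        Opaque name of the common space; two grids are only comparable when
        they share it.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    space_id: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive numbers, got {self.spacing}")
        bad = np.count_nonzero(~np.isfinite(self.data))
        if bad:
            raise ValueError(f"volume contains {bad} non-finite voxel(s)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def compatible(self, other: "VolumeGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and self.space_id == other.space_id
        )

    def like(self, data: np.ndarray) -> "VolumeGrid":
        """A new volume with the same grid metadata and different data."""
        return VolumeGrid(data, self.spacing, self.space_id)


def save_volume(vol: VolumeGrid, path: str | Path) -> Path:
    """Write a VolumeGrid as NIfTI; space_id is stored in the descrip field."""
    path = Path(path)
    affine = np.diag(list(vol.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing)
    img.header["descrip"] = vol.space_id.encode()[:79]
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> VolumeGrid:
    """Load a 3D NIfTI volume.

    Raises on missing files, non-3D images, and non-finite voxels (the voxel
    count is reported rather than silently zeroed).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.ndim}D")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    bad = np.count_nonzero(~np.isfinite(data))
    if bad:
        raise ValueError(f"{path}: {bad} non-finite voxel(s)")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode(errors="replace")
    return VolumeGrid(data, spacing, space_id=descrip or "unknown")


def assert_cohort_compatible(volumes: Sequence[VolumeGrid]) -> None:
    """Check that all grids are pairwise compatible.

    The error names the first mismatching pair; voxel-wise statistics across
    an incompatible cohort would be meaningless.
    """
    if len(volumes) == 0:
        raise ValueError("empty cohort: no volumes to compare")
    ref = volumes[0]
    for i, v in enumerate(volumes[1:], start=1):
        if not ref.compatible(v):
            raise ValueError(
                "incompatible grids between volume 0 "
                f"(shape={ref.shape}, spacing={ref.spacing}, space={ref.space_id!r}) "
                f"and volume {i} (shape={v.shape}, spacing={v.spacing}, "
                f"space={v.space_id!r})"
            )


def validate_subjects_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the cohort table contract.

    Requires the fixed group vocabulary, non-negative visit times, and a
    baseline (visit_time 0) row for every subject.
    """
    missing = [c for c in SUBJECTS_COLUMNS[:3] if c not in table.columns]
    if missing:
        raise ValueError(f"subjects table missing columns: {missing}")
    bad_groups = set(table["group"]) - set(GROUPS)
    if bad_groups:
        raise ValueError(f"unknown group labels {sorted(bad_groups)}; allowed: {GROUPS}")
    if (table["visit_time_years"] < 0).any():
        raise ValueError("visit_time_years must be >= 0")
    no_baseline = [
        sid
        for sid, sub in table.groupby("subject_id")
        if not np.isclose(sub["visit_time_years"].min(), 0.0)
    ]
    if no_baseline:
        raise ValueError(f"subjects without a baseline (t=0) row: {no_baseline}")
    return table


def read_subjects_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    return validate_subjects_table(table)


def write_subjects_table(table: pd.DataFrame, path: str | Path) -> Path:
    validate_subjects_table(table)
    path = Path(path)
    table.to_csv(path, sep="\t", index=False)
    return path
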