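"""Shared in-memory containers: series metadata, volumes, slice samples."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from nibabel import orientations as nibo


@dataclass
class SeriesMetadata:
    """The DICOM header fields the pipeline reads.

    Every field except the UIDs may be absent (``None``): anonymized or
    exotic exports routinely drop tags, and absence must stay observable —
    no field is ever filled with a fabricated default.
    """

    series_uid: str = ""
    series_description: Optional[str] = None
    study_description: Optional[str] = None
    image_type: Optional[list[str]] = None
    repetition_time_ms: Optional[float] = None
    echo_time_ms: Optional[float] = None
    rows: Optional[int] = None
    cols: Optional[int] = None
    direction_cosines: Optional[tuple[float, ...]] = None  # 6 floats, row then col
    acquisition_type: Optional[str] = None  # "2D" or "3D"
    subject_id: Optional[str] = None
    session_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.direction_cosines is not None:
            dc = np.asarray(self.direction_cosines, dtype=float)
            if dc.shape != (6,):
                raise ValueError("direction_cosines must have exactly 6 entries")
            row, col = dc[:3], dc[3:]
            if abs(np.linalg.norm(row) - 1) > 1e-3 or abs(np.linalg.norm(col) - 1) > 1e-3:
                raise ValueError("direction cosines must be unit vectors")
            if abs(float(row @ col)) > 1e-3:
                raise ValueError("direction cosine vectors must be orthogonal")
            self.direction_cosines = tuple(float(v) for v in dc)


@dataclass
class Volume:
    """A rank-3 or rank-4 voxel grid with physical geometry.

    ``voxels`` is indexed ``(i, j, k[, t])``; ``affine`` is a 4x4 matrix
    mapping voxel indices of the first three axes to RAS+ millimetres, the
    convention shared with NIfTI.  Spacing and anatomical axis codes are
    derived from the affine rather than stored separately, so they can
    never disagree with it.
    """

    voxels: np.ndarray
    affine: np.ndarray
    metadata: Optional[SeriesMetadata] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim not in (3, 4):
            raise ValueError(f"volume must be rank 3 or 4, got rank {self.voxels.ndim}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def is_4d(self) -> bool:
        return self.voxels.ndim == 4

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    @property
    def spacing_mm(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def axis_orientation(self) -> tuple[str, str, str]:
        """Anatomical direction each voxel axis points towards, e.g. ('R','A','S')."""
        return tuple(nibo.aff2axcodes(self.affine))

    def physical_extent_mm(self) -> np.ndarray:
        """Field of view per spatial axis (size x spacing)."""
        return np.asarray(self.voxels.shape[:3]) * self.spacing_mm


@dataclass
class SliceSample:
    """One intensity-scaled 256x256 slice — the CNN's unit of input."""

    pixels: np.ndarray
    four_d_label: int
    scan_id: str
    slice_index: int
    true_class: Optional[str] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValueError("slice pixels must be 2-D")
        if self.four_d_label not in (0, 1):
            raise ValueError("four_d_label must be 0 or 1")
        if self.slice_index < 0:
            raise ValueError("slice_index must be non-negative")


@dataclass
class ScanPrediction:
    """Scan-level decision aggregated from per-slice class probabilities."""

    scan_id: str
    predicted_class: str
    vote_counts: np.ndarray
    mean_probabilities: np.ndarray
    tie_broken: bool = False
    orientation: Optional[str] = None

    def __post_init__(self) -> None:
        self.vote_counts = np.asarray(self.vote_counts, dtype=int)
        self.mean_probabilities = np.asarray(self.mean_probabilities, dtype=float)


def validate_probabilities(p: Sequence[float], atol: float = 1e-5) -> np.ndarray:
    """Check an 8-class probability vector: non-negative, sums to one."""
    arr = np.asarray(p, dtype=float)
    if arr.shape[-1] != 8:
        raise ValueError("class probabilities must have 8 entries")
    if np.any(arr < -atol):
        raise ValueError("class probabilities must be non-negative")
    if np.any(np.abs(arr.sum(axis=-1) - 1.0) > atol):
        raise ValueError("class probabilities must sum to 1")
    return arr
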