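"""DICOM and NIfTI input/output.

Reads unstructured DICOM trees into :class:`~scansorter.types.Volume`
objects (grouping files by series UID, stacking frames by their position
along the slice normal, and detecting a fourth temporal/b-value
dimension), writes phantom volumes back out as standard-conformant DICOM
series, and round-trips NIfTI-1 files.  This is the package's internal
replacement for an external DICOM-to-NIfTI converter.

Geometry conventions
--------------------
DICOM patient coordinates are LPS+; ``Volume.affine`` is RAS+ (the NIfTI
convention), so the first two spatial axes are negated when building the
affine from DICOM direction cosines.  Pixel arrays arrive as
``(rows, cols)``; volumes are indexed ``(i, j, k)`` with ``i`` the column
index and ``j`` the row index, so that the affine columns are simply the
scaled row/column direction cosines.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import nibabel as nib
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

from .types import SeriesMetadata, Volume

logger = logging.getLogger(__name__)

_LPS_TO_RAS = np.diag([-1.0, -1.0, 1.0])

#: maximum relative spread of slice gaps before a series is rejected
SLICE_SPACING_TOLERANCE = 0.01


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def scan_directory(root: os.PathLike | str) -> dict[str, list[Path]]:
    """Group every parseable DICOM file under ``root`` by SeriesInstanceUID.

    Non-DICOM files are skipped with a logged warning.  An empty result is
    returned (not an error) when no DICOM files are found.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"directory does not exist: {root}")
    groups: dict[str, list[Path]] = {}
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        try:
            ds = pydicom.dcmread(path, stop_before_pixels=True,
                                 specific_tags=["SeriesInstanceUID"])
        except Exception:
            logger.warning("skipping non-DICOM file: %s", path)
            continue
        uid = str(getattr(ds, "SeriesInstanceUID", "")) or "unknown-series"
        groups.setdefault(uid, []).append(path)
    return groups


def _read_group(files: Sequence[os.PathLike | str]) -> list[pydicom.Dataset]:
    if not files:
        raise ValueError("empty file group")
    return [pydicom.dcmread(f) for f in files]


def _frame_float(ds: pydicom.Dataset) -> np.ndarray:
    if "PixelData" not in ds:
        raise ValueError(f"missing pixel data in {getattr(ds, 'filename', '<dataset>')}")
    arr = ds.pixel_array.astype(np.float32)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept


def _temporal_index(ds: pydicom.Dataset) -> Optional[int]:
    for tag in ("TemporalPositionIdentifier", "AcquisitionNumber"):
        v = getattr(ds, tag, None)
        if v not in (None, ""):
            return int(v)
    return None


def assemble_volume(files: Sequence[os.PathLike | str]) -> Volume:
    """Stack a series' single-frame DICOM files into a 3-D or 4-D volume.

    Frames are ordered by the projection of ImagePositionPatient onto the
    slice normal.  Repeated positions combined with a temporal/b-value
    index tag produce a rank-4 ``(i, j, k, t)`` volume; repeated positions
    without such a tag are ambiguous and rejected.
    """
    datasets = _read_group(files)
    if len(datasets) < 2:
        raise ValueError("assemble_volume needs at least 2 files in a series")

    rows = {int(ds.Rows) for ds in datasets}
    cols = {int(ds.Columns) for ds in datasets}
    if len(rows) != 1 or len(cols) != 1:
        raise ValueError(
            f"inconsistent frame sizes within series: rows={sorted(rows)} cols={sorted(cols)}"
        )

    first = datasets[0]
    iop = getattr(first, "ImageOrientationPatient", None)
    if iop is None:
        raise ValueError("series lacks ImageOrientationPatient; cannot stack frames")
    iop = np.asarray([float(v) for v in iop])
    row_cos, col_cos = iop[:3], iop[3:]
    normal = np.cross(row_cos, col_cos)

    # projection of each frame position onto the slice normal
    entries = []
    for ds in datasets:
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is None:
            raise ValueError("frame lacks ImagePositionPatient")
        pos = np.asarray([float(v) for v in ipp])
        entries.append((float(normal @ pos), pos, _temporal_index(ds), ds))

    projections = np.asarray([e[0] for e in entries])
    # group frames whose positions coincide (within 1e-3 mm along the normal)
    order = np.argsort(projections, kind="stable")
    unique_projs: list[float] = []
    groups: list[list[int]] = []
    for idx in order:
        p = projections[idx]
        if unique_projs and abs(p - unique_projs[-1]) < 1e-3:
            groups[-1].append(int(idx))
        else:
            unique_projs.append(float(p))
            groups.append([int(idx)])

    n_slices = len(groups)
    counts = {len(g) for g in groups}
    if len(counts) != 1:
        raise ValueError(
            "ambiguous series structure: slice positions repeat unevenly "
            f"(frames per position: {sorted(counts)})"
        )
    n_t = counts.pop()
    if n_t > 1:
        for g in groups:
            if any(entries[i][2] is None for i in g):
                raise ValueError(
                    "ambiguous series structure: repeated slice positions "
                    "without a temporal/b-value index tag"
                )
            g.sort(key=lambda i: entries[i][2])

    if n_slices < 2:
        raise ValueError("series collapses to fewer than 2 distinct slice positions")

    gaps = np.diff(unique_projs)
    mean_gap = float(np.mean(gaps))
    if mean_gap <= 0:
        raise ValueError("degenerate slice positions")
    rel = np.abs(gaps - mean_gap) / mean_gap
    worst = int(np.argmax(rel))
    if rel[worst] > SLICE_SPACING_TOLERANCE:
        raise ValueError(
            f"non-uniform slice spacing: gap {gaps[worst]:.4f} mm between slice "
            f"{worst} and {worst + 1} (mean gap {mean_gap:.4f} mm)"
        )

    nr, nc = rows.pop(), cols.pop()
    shape = (nc, nr, n_slices) + ((n_t,) if n_t > 1 else ())
    vox = np.empty(shape, dtype=np.float32)
    for k, g in enumerate(groups):
        for t, idx in enumerate(g):
            frame = _frame_float(entries[idx][3])  # (rows, cols)
            if n_t > 1:
                vox[:, :, k, t] = frame.T
            else:
                vox[:, :, k] = frame.T

    ps = getattr(first, "PixelSpacing", [1.0, 1.0])
    row_spacing, col_spacing = float(ps[0]), float(ps[1])
    origin = entries[groups[0][0]][1]
    affine = np.eye(4)
    affine[:3, 0] = _LPS_TO_RAS @ (row_cos * col_spacing)
    affine[:3, 1] = _LPS_TO_RAS @ (col_cos * row_spacing)
    affine[:3, 2] = _LPS_TO_RAS @ (normal * mean_gap)
    affine[:3, 3] = _LPS_TO_RAS @ origin

    return Volume(vox, affine, metadata=extract_metadata(files, _datasets=datasets))


def _none_if_missing(ds: pydicom.Dataset, keyword: str):
    v = getattr(ds, keyword, None)
    if v in (None, ""):
        return None
    return v


def extract_metadata(files: Sequence[os.PathLike | str], *,
                     _datasets: Optional[list[pydicom.Dataset]] = None) -> SeriesMetadata:
    """Read the header fields the classifier and sorter use.

    Absent tags map to absent fields — nothing is defaulted, because the
    heuristic baseline must be able to observe missing metadata.
    """
    if _datasets is None:
        if not files:
            raise ValueError("empty file group")
        ds = pydicom.dcmread(Path(files[0]), stop_before_pixels=True)
    else:
        ds = _datasets[0]

    image_type = _none_if_missing(ds, "ImageType")
    if image_type is not None:
        image_type = [str(t) for t in image_type]
    tr = _none_if_missing(ds, "RepetitionTime")
    te = _none_if_missing(ds, "EchoTime")
    iop = _none_if_missing(ds, "ImageOrientationPatient")
    return SeriesMetadata(
        series_uid=str(_none_if_missing(ds, "SeriesInstanceUID") or ""),
        series_description=_none_if_missing(ds, "SeriesDescription"),
        study_description=_none_if_missing(ds, "StudyDescription"),
        image_type=image_type,
        repetition_time_ms=None if tr is None else float(tr),
        echo_time_ms=None if te is None else float(te),
        rows=None if _none_if_missing(ds, "Rows") is None else int(ds.Rows),
        cols=None if _none_if_missing(ds, "Columns") is None else int(ds.Columns),
        direction_cosines=None if iop is None else tuple(float(v) for v in iop),
        acquisition_type=_none_if_missing(ds, "MRAcquisitionType"),
        subject_id=_none_if_missing(ds, "PatientID"),
        session_id=_none_if_missing(ds, "StudyInstanceUID"),
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

# frame extraction per acquisition orientation: given a canonical (i,j,k)
# volume, each orientation defines the in-plane axes and the stacking axis.
_ORIENT_COSINES = {
    # orientation -> (row cosines, column cosines, slice normal) in LPS
    "axial": ((1, 0, 0), (0, 1, 0), (0, 0, 1)),
    "threeD": ((1, 0, 0), (0, 1, 0), (0, 0, 1)),
    "coronal": ((1, 0, 0), (0, 0, -1), (0, 1, 0)),
    "sagittal": ((0, 1, 0), (0, 0, -1), (1, 0, 0)),
}


def _slice_frames(vol3: np.ndarray, orientation: str) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Return frames (n_slices, rows, cols) and the (dx_row, dx_col, dx_slice)
    axis mapping used for spacing, for one 3-D block."""
    if orientation in ("axial", "threeD"):
        # frame[r, c] = vol[c, r, s]
        frames = np.transpose(vol3, (2, 1, 0))
        axes = (1, 0, 2)  # rows step axis, cols step axis, slice axis
    elif orientation == "coronal":
        # frame[r, c] = vol[c, s, zmax - r]
        frames = np.transpose(vol3[:, :, ::-1], (1, 2, 0))
        axes = (2, 0, 1)
    elif orientation == "sagittal":
        # frame[r, c] = vol[s, c, zmax - r]
        frames = np.transpose(vol3[:, :, ::-1], (0, 2, 1))
        axes = (2, 1, 0)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    return np.ascontiguousarray(frames), axes


def _ds_str(value: float) -> str:
    """Format a float for a DICOM DS element (16 char limit)."""
    s = f"{value:.10g}"
    return s[:16]


def write_dicom_series(vol: Volume, meta: SeriesMetadata, dest: os.PathLike | str,
                       orientation: str = "axial") -> list[Path]:
    """Write a volume as a single-frame-per-file DICOM series.

    Pixel data is stored as 16-bit unsigned integers with a linear rescale
    (RescaleSlope/Intercept) so readers recover the original floats to
    within one quantization step.  Rank-4 volumes emit one file per
    (slice, time point) with a TemporalPositionIdentifier.  Output is
    byte-identical across runs for identical inputs: UIDs are derived
    deterministically from the series UID and dates are fixed.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    vox = vol.voxels
    if vox.ndim == 3:
        vox = vox[..., np.newaxis]
    n_t = vox.shape[3]
    spacing = vol.spacing_mm

    vmin = float(vox.min())
    vmax = float(vox.max())
    if vmax <= vmin:
        slope, intercept = 1.0, vmin
        quantized = np.zeros(vox.shape, dtype=np.uint16)
    else:
        slope = (vmax - vmin) / 65535.0
        intercept = vmin
        quantized = np.round((vox - vmin) / slope).astype(np.uint16)

    row_cos, col_cos, normal = (np.asarray(v, dtype=float) for v in _ORIENT_COSINES[orientation])
    # patient-space position of frame pixel (0, 0) at slice 0: the coronal and
    # sagittal layouts flip the third volume axis, so their frames start at its top
    nz = vox.shape[2]
    if orientation in ("axial", "threeD"):
        base = np.zeros(3)
    elif orientation == "coronal":
        base = np.array([0.0, 0.0, (nz - 1) * spacing[2]])
    else:  # sagittal
        base = np.array([0.0, 0.0, (nz - 1) * spacing[2]])
    series_uid = meta.series_uid or generate_uid()
    study_uid = meta.session_id or generate_uid(entropy_srcs=[series_uid, "study"])

    paths: list[Path] = []
    instance = 0
    for t in range(n_t):
        frames, (row_ax, col_ax, slice_ax) = _slice_frames(quantized[:, :, :, t], orientation)
        n_slices = frames.shape[0]
        d_slice = spacing[slice_ax]
        for k in range(n_slices):
            instance += 1
            ds = Dataset()
            ds.SOPClassUID = MRImageStorage
            ds.SOPInstanceUID = generate_uid(entropy_srcs=[series_uid, str(instance)])
            ds.Modality = "MR"
            ds.PatientName = meta.subject_id or "anon"
            ds.PatientID = meta.subject_id or "anon"
            ds.StudyInstanceUID = study_uid
            ds.SeriesInstanceUID = series_uid
            ds.StudyID = "1"
            ds.SeriesNumber = 1
            ds.InstanceNumber = instance
            ds.StudyDate = "20200101"
            ds.StudyTime = "120000"
            if meta.study_description is not None:
                ds.StudyDescription = meta.study_description
            if meta.series_description is not None:
                ds.SeriesDescription = meta.series_description
            if meta.image_type is not None:
                ds.ImageType = list(meta.image_type)
            if meta.repetition_time_ms is not None:
                ds.RepetitionTime = _ds_str(meta.repetition_time_ms)
            if meta.echo_time_ms is not None:
                ds.EchoTime = _ds_str(meta.echo_time_ms)
            if meta.acquisition_type is not None:
                ds.MRAcquisitionType = meta.acquisition_type

            frame = frames[k]
            ds.Rows, ds.Columns = frame.shape
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 16
            ds.BitsStored = 16
            ds.HighBit = 15
            ds.PixelRepresentation = 0
            ds.RescaleSlope = _ds_str(slope)
            ds.RescaleIntercept = _ds_str(intercept)
            ds.PixelSpacing = [_ds_str(spacing[row_ax]), _ds_str(spacing[col_ax])]
            ds.SliceThickness = _ds_str(d_slice)
            ds.ImageOrientationPatient = [_ds_str(v) for v in (*row_cos, *col_cos)]
            ds.ImagePositionPatient = [_ds_str(v) for v in base + normal * (k * d_slice)]
            if n_t > 1:
                ds.TemporalPositionIdentifier = t + 1
                ds.NumberOfTemporalPositions = n_t
            ds.PixelData = frame.tobytes()

            fm = FileMetaDataset()
            fm.MediaStorageSOPClassUID = ds.SOPClassUID
            fm.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
            fm.TransferSyntaxUID = ExplicitVRLittleEndian
            ds.file_meta = fm

            path = dest / f"IM-{instance:05d}.dcm"
            ds.save_as(path, enforce_file_format=True)
            paths.append(path)
    return paths


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _orthogonalize_direction(affine: np.ndarray) -> np.ndarray:
    """Replace the 3x3 direction block with its nearest orthogonal factor,
    preserving the per-axis voxel spacings."""
    A = affine[:3, :3]
    spacing = np.linalg.norm(A, axis=0)
    U, _, Vt = np.linalg.svd(A)
    R = U @ Vt  # nearest orthogonal matrix (polar factor)
    out = affine.copy()
    out[:3, :3] = R * spacing[np.newaxis, :]
    return out


def read_nifti(path: os.PathLike | str) -> Volume:
    """Load a NIfTI-1 volume.

    Affines with shear beyond 1e-3 (non-orthogonal direction columns) are
    replaced by the nearest orthogonal orientation, with a logged warning.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    if data.ndim not in (3, 4):
        raise ValueError(f"unsupported NIfTI rank {data.ndim} in {path}")
    affine = np.asarray(img.affine, dtype=float)
    A = affine[:3, :3]
    spacing = np.linalg.norm(A, axis=0)
    if np.any(spacing <= 0):
        raise ValueError(f"degenerate affine in {path}")
    Rn = A / spacing[np.newaxis, :]
    shear = np.max(np.abs(Rn.T @ Rn - np.eye(3)))
    if shear > 1e-3:
        logger.warning(
            "NIfTI affine of %s is non-orthogonal (shear %.2e); "
            "using nearest orthogonal orientation", path, shear,
        )
        affine = _orthogonalize_direction(affine)
    return Volume(data, affine)


def write_nifti(vol: Volume, path: os.PathLike | str) -> Path:
    """Write a volume as float32 NIfTI-1 (.nii or .nii.gz)."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float32), vol.affine)
    img.header.set_zooms(tuple(vol.spacing_mm) + ((1.0,) if vol.is_4d else ()))
    nib.save(img, str(path))
    return path


def dicom_tree_to_nifti(root: os.PathLike | str, out_dir: os.PathLike | str) -> dict[str, Path]:
    """Convert every DICOM series under ``root`` to a NIfTI file.

    Returns a mapping from series UID to the written path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for uid, files in scan_directory(root).items():
        vol = assemble_volume(files)
        written[uid] = write_nifti(vol, out_dir / f"{uid}.nii.gz")
    return written
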