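"""Standardize any input scan into 25 slice samples of 256x256 in [0, 1].

The chain is: reduce a 4-D scan to its first temporal element (keeping a
binary "was 4-D" label as an extra classifier feature), reorient to
canonical RAS axes by pure axis permutation/flips, resample to a fixed
256x256x25 grid with cubic b-spline interpolation while preserving the
physical field of view, split into 25 axial planes and min-max scale each
slice independently.  No augmentation, skull stripping or registration is
applied.

Grid convention for resampling: the first and last output voxel *edges*
coincide with the input's physical extent, i.e. output sample ``j`` along
an axis sits at input index ``(j + 0.5) * n_in / n_out - 0.5``.  This
makes identity resampling exact and keeps ``size * spacing`` invariant to
floating-point round-off.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from nibabel import orientations as nibo
from scipy import ndimage

from .types import SliceSample, Volume

TARGET_SHAPE = (256, 256, 25)
N_SLICES = TARGET_SHAPE[2]


def detect_and_reduce_4d(vol: Volume) -> tuple[Volume, int]:
    """Extract the first temporal element of a 4-D scan; tag it with 1.

    Dimensionality, not temporal extent, decides the label: a rank-4
    volume with a single time point is still labelled 4-D.
    """
    if vol.voxels.ndim == 4:
        return Volume(vol.voxels[..., 0], vol.affine, vol.metadata), 1
    if vol.voxels.ndim == 3:
        return vol, 0
    raise ValueError(f"expected a rank-3 or rank-4 volume, got rank {vol.voxels.ndim}")


def reorient_to_canonical(vol: Volume) -> Volume:
    """Permute/flip axes (no interpolation) so the volume is RAS-ordered:
    axis 0 left->right, axis 1 posterior->anterior, axis 2 inferior->superior."""
    if vol.affine is None:
        raise ValueError(
            "volume orientation unknown: supply an affine (from DICOM direction "
            "cosines or a NIfTI header) before reorienting"
        )
    ornt = nibo.io_orientation(vol.affine)
    if np.any(np.isnan(ornt)):
        raise ValueError("volume orientation could not be determined from the affine")
    vox = nibo.apply_orientation(vol.voxels, ornt)
    affine = vol.affine @ nibo.inv_ornt_aff(ornt, vol.voxels.shape[:3])
    return Volume(np.ascontiguousarray(vox), affine, vol.metadata)


def _sample_coords(n_in: int, n_out: int) -> np.ndarray:
    return (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5


def _cubic_bspline(u: np.ndarray) -> np.ndarray:
    a = np.abs(u)
    return np.where(
        a < 1, (4 - 6 * a ** 2 + 3 * a ** 3) / 6,
        np.where(a < 2, (2 - a) ** 3 / 6, 0.0),
    )


def _weight_matrix(n_in: int, n_out: int, order: int) -> np.ndarray:
    """(n_out, n_in) interpolation weights along one axis.

    Output sample centres follow the extent-preserving grid convention;
    coordinates outside the input support are clamped to the edge sample,
    and basis taps beyond the array accumulate onto the edge coefficient
    (replicate-edge boundary handling).
    """
    x = np.clip(_sample_coords(n_in, n_out), 0.0, n_in - 1.0)
    W = np.zeros((n_out, n_in))
    if order == 0:
        idx = np.clip(np.floor(x + 0.5).astype(int), 0, n_in - 1)
        W[np.arange(n_out), idx] = 1.0
    elif order == 1:
        i0 = np.clip(np.floor(x).astype(int), 0, n_in - 1)
        i1 = np.minimum(i0 + 1, n_in - 1)
        t = x - i0
        np.add.at(W, (np.arange(n_out), i0), 1.0 - t)
        np.add.at(W, (np.arange(n_out), i1), t)
    elif order == 3:
        base = np.floor(x).astype(int)
        for off in (-1, 0, 1, 2):
            idx = base + off
            w = _cubic_bspline(x - idx)
            np.add.at(W, (np.arange(n_out), np.clip(idx, 0, n_in - 1)), w)
    else:
        raise ValueError(f"unsupported interpolation order {order}")
    return W


def _resample_axis(arr: np.ndarray, axis: int, W: np.ndarray) -> np.ndarray:
    moved = np.moveaxis(arr, axis, 0)
    out = np.tensordot(W, moved, axes=(1, 0))
    return np.moveaxis(out, 0, axis)


def resample_fixed_grid(vol: Volume, target_shape: tuple[int, int, int] = TARGET_SHAPE,
                        order: int = 3) -> Volume:
    """Resample onto a fixed grid spanning the same physical extent.

    ``order=3`` (default) is cubic b-spline interpolation: the input is
    prefiltered into b-spline coefficients and then evaluated separably —
    one small weight-matrix product per axis, since the target grid is
    axis-aligned.  ``order=0`` gives plain nearest-neighbour (used for
    oracle validation); ``order=1`` trilinear.  Sample positions outside
    the input support are clamped to the edge.
    """
    if vol.voxels.ndim != 3:
        raise ValueError("resample_fixed_grid expects a rank-3 volume")
    shape_in = vol.voxels.shape
    if np.any(vol.spacing_mm <= 0):
        raise ValueError("degenerate voxel spacing")
    data = vol.voxels.astype(np.float64)
    if order == 3:
        data = ndimage.spline_filter(data, order=3, mode="nearest")
    out = data
    for axis in range(3):
        out = _resample_axis(out, axis, _weight_matrix(shape_in[axis],
                                                       target_shape[axis], order))
    out = out.astype(np.float32)

    # same direction columns, rescaled so extent (size * spacing) is conserved
    affine = vol.affine.copy()
    for i in range(3):
        affine[:3, i] = vol.affine[:3, i] * (shape_in[i] / target_shape[i])
    first = np.array([_sample_coords(shape_in[i], target_shape[i])[0]
                      for i in range(3)] + [1.0])
    affine[:3, 3] = (vol.affine @ first)[:3]
    return Volume(out, affine, vol.metadata)


def _scale_slice(plane: np.ndarray) -> np.ndarray:
    mn = float(plane.min())
    mx = float(plane.max())
    if mx <= mn:
        return np.zeros_like(plane, dtype=np.float32)
    return ((plane - mn) / (mx - mn)).astype(np.float32)


def split_and_scale(vol: Volume, four_d_label: int, scan_id: str = "",
                    true_class: Optional[str] = None) -> list[SliceSample]:
    """Split a 256x256x25 volume into 25 independently min-max scaled slices.

    A constant slice (min == max leaves the scaling undefined) maps to all
    zeros — a class-neutral value rather than a failure.
    """
    if tuple(vol.voxels.shape) != TARGET_SHAPE:
        raise ValueError(f"expected shape {TARGET_SHAPE}, got {vol.voxels.shape}")
    return [
        SliceSample(
            pixels=_scale_slice(vol.voxels[:, :, i]),
            four_d_label=four_d_label,
            scan_id=scan_id,
            slice_index=i,
            true_class=true_class,
        )
        for i in range(N_SLICES)
    ]


def preprocess_scan(vol: Volume, scan_id: str = "",
                    true_class: Optional[str] = None) -> list[SliceSample]:
    """Full preprocessing chain: 4-D reduction, reorientation, fixed-grid
    resampling, slice split and per-slice intensity scaling.

    Always yields exactly 25 samples sharing ``scan_id`` and the 4-D label.
    """
    vol3, four_d = detect_and_reduce_4d(vol)
    vol3 = reorient_to_canonical(vol3)
    vol3 = resample_fixed_grid(vol3)
    return split_and_scale(vol3, four_d, scan_id=scan_id, true_class=true_class)


# ---------------------------------------------------------------------------
# on-disk sample cache
# ---------------------------------------------------------------------------

CACHE_MANIFEST_COLUMNS = ["scan_id", "path", "four_d_label", "true_class"]


def save_samples(samples: Sequence[SliceSample], path: os.PathLike | str) -> Path:
    """Store one scan's 25 slices as a compressed npz."""
    path = Path(path)
    pixels = np.stack([s.pixels for s in samples]).astype(np.float32)
    np.savez_compressed(
        path,
        pixels=pixels,
        four_d_label=np.int8(samples[0].four_d_label),
        scan_id=np.str_(samples[0].scan_id),
        true_class=np.str_(samples[0].true_class or ""),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_samples(path: os.PathLike | str) -> list[SliceSample]:
    with np.load(path, allow_pickle=False) as z:
        pixels = z["pixels"]
        four_d = int(z["four_d_label"])
        scan_id = str(z["scan_id"])
        true_class = str(z["true_class"]) or None
    return [
        SliceSample(pixels[i], four_d, scan_id, i, true_class)
        for i in range(pixels.shape[0])
    ]


def write_cache(scans: Iterable[Sequence[SliceSample]],
                cache_dir: os.PathLike | str) -> pd.DataFrame:
    """Persist many preprocessed scans; returns (and writes) the cache manifest."""
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for samples in scans:
        scan_id = samples[0].scan_id
        safe = "".join(ch if ch.isalnum() or ch in "._-" else "_" for ch in scan_id)
        path = save_samples(samples, cache_dir / f"{safe}.npz")
        rows.append({
            "scan_id": scan_id,
            "path": str(path),
            "four_d_label": samples[0].four_d_label,
            "true_class": samples[0].true_class or "",
        })
    manifest = pd.DataFrame(rows, columns=CACHE_MANIFEST_COLUMNS)
    manifest.to_csv(cache_dir / "samples.tsv", sep="\t", index=False)
    return manifest
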