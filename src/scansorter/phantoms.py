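"""Synthetic brain phantoms for all eight scan types.

The generator renders a concentric-ellipsoid head model (skull shell, CSF
rim, grey-matter shell, white-matter core, ellipsoidal ventricles, two
anterior eye spheres, optional lesion) and assigns each tissue a
class-specific mean intensity, so the resulting images carry the
tissue-contrast orderings that distinguish the scan types in real MRI:
bright CSF on T2w, suppressed CSF on FLAIR, a contrast-enhancing lesion
rim on T1wC, diffusion attenuation and ghosting artifacts on DWI, a bolus
signal dip on DSC perfusion, and a smooth parametric field for derived
maps.  Everything is deterministic given the spec's seed, and series are
written as standard DICOM so the full pipeline — conversion, training,
prediction, sorting — runs without any external data.

The contrast table is a design fixture, not a physical model: values were
chosen once so that any two classes remain distinguishable at the default
noise level while staying qualitatively faithful to real contrast
orderings.  It lives in :data:`CONTRAST_TABLE` and can be overridden per
call.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .dicom_io import write_dicom_series
from .labels import CLASS_LABELS, FOUR_D_CAPABLE, ORIENTATIONS
from .types import SeriesMetadata, Volume

__all__ = [
    "PhantomSpec", "TissueMap", "CONTRAST_TABLE", "TISSUES",
    "generate_tissue_map", "render_scan", "write_dicom_series",
    "generate_dataset", "MANIFEST_COLUMNS",
]

# tissue label codes
TISSUES = {
    "background": 0,
    "skull": 1,
    "CSF": 2,
    "GM": 3,
    "WM": 4,
    "eyes": 5,
    "lesion": 6,
}

#: per-class mean intensity of each tissue, on a [0, 1] scale.  The skull
#: compartment doubles as scalp, whose fat signal varies strongly across
#: sequences; values were fixed once so that every pair of classes stays
#: histogram-separable (pairwise within-head KS > 0.2) at the default
#: noise level while preserving the canonical contrast orderings (bright
#: CSF on T2w, suppressed CSF on FLAIR, enhancing rim on T1wC, ...).
CONTRAST_TABLE: dict[str, dict[str, float]] = {
    "T1w":       {"background": 0.02, "skull": 0.70, "CSF": 0.20, "GM": 0.60,
                  "WM": 0.80, "eyes": 0.30, "lesion": 0.55},
    # post-contrast: enhancing lesion rim, mildly elevated soft tissue,
    # enhancing scalp vessels and ocular choroid
    "T1wC":      {"background": 0.02, "skull": 0.85, "CSF": 0.25, "GM": 0.62,
                  "WM": 0.82, "eyes": 0.48, "lesion": 0.55, "lesion_rim": 0.95},
    "T2w":       {"background": 0.02, "skull": 0.35, "CSF": 0.95, "GM": 0.60,
                  "WM": 0.40, "eyes": 0.90, "lesion": 0.75},
    "PDw":       {"background": 0.02, "skull": 0.50, "CSF": 0.65, "GM": 0.70,
                  "WM": 0.60, "eyes": 0.65, "lesion": 0.68},
    "T2w-FLAIR": {"background": 0.02, "skull": 0.25, "CSF": 0.10, "GM": 0.60,
                  "WM": 0.45, "eyes": 0.35, "lesion": 0.85},
    "DWI":       {"background": 0.02, "skull": 0.05, "CSF": 0.15, "GM": 0.65,
                  "WM": 0.60, "eyes": 0.25, "lesion": 0.70},
    "PWI-DSC":   {"background": 0.02, "skull": 0.12, "CSF": 0.30, "GM": 0.50,
                  "WM": 0.38, "eyes": 0.30, "lesion": 0.45},
    "derived":   {},  # rendered as a smooth parametric field, see _render_derived
}

MANIFEST_COLUMNS = ["path", "subject", "session", "scan_type", "orientation", "is_4d"]


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic scan; identical specs render
    byte-identical outputs."""

    scan_type: str
    grid_shape: tuple[int, int, int] = (64, 64, 36)
    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 4.0)
    orientation: str = "axial"
    n_temporal: int = 1
    noise_sd: float = 0.03
    ghosting: Optional[bool] = None  # None: on for DWI / PWI-DSC / derived
    lesion: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_type not in CLASS_LABELS:
            raise ValueError(f"unknown scan type {self.scan_type!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive reals")
        if self.n_temporal < 1:
            raise ValueError("n_temporal must be >= 1")
        if self.n_temporal > 1 and self.scan_type not in FOUR_D_CAPABLE:
            raise ValueError(
                f"n_temporal > 1 is only valid for {sorted(FOUR_D_CAPABLE)}, "
                f"not {self.scan_type!r}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def ghosting_enabled(self) -> bool:
        if self.ghosting is not None:
            return self.ghosting
        return self.scan_type in ("DWI", "PWI-DSC", "derived")


@dataclass
class TissueMap:
    """Voxel-wise tissue labels for one phantom (codes in :data:`TISSUES`)."""

    labels: np.ndarray

    def count(self, tissue: str) -> int:
        return int(np.count_nonzero(self.labels == TISSUES[tissue]))

    def mask(self, tissue: str) -> np.ndarray:
        return self.labels == TISSUES[tissue]

    @property
    def head_mask(self) -> np.ndarray:
        return self.labels != TISSUES["background"]


def _normalized_coords(shape: tuple[int, int, int]) -> tuple[np.ndarray, ...]:
    """Open grids of coordinates in [-1, 1] along each axis."""
    return tuple(
        np.linspace(-1.0, 1.0, n).reshape([-1 if i == ax else 1 for i in range(3)])
        for ax, n in enumerate(shape)
    )


def generate_tissue_map(spec: PhantomSpec) -> TissueMap:
    """Render the concentric-ellipsoid head model for one phantom.

    Geometry is lightly jittered from the spec seed so different subjects
    are not voxel-identical, but the same spec always yields the same map.
    """
    shape = tuple(int(n) for n in spec.grid_shape)
    if any(n < 32 for n in shape):
        raise ValueError(
            f"grid {shape} too small: every axis must be >= 32 voxels so all "
            "head compartments (skull, CSF rim, GM, WM, ventricles, eyes) fit"
        )
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    j = lambda scale=0.05: 1.0 + rng.uniform(-scale, scale)

    x, y, z = _normalized_coords(shape)
    # head ellipsoid radius field; rho = 1 at the outer skull surface
    a, b, c = 0.85 * j(), 0.90 * j(), 0.80 * j()
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[rho <= 1.00] = TISSUES["skull"]
    labels[rho <= 0.88] = TISSUES["CSF"]      # CSF rim inside the skull
    labels[rho <= 0.78] = TISSUES["GM"]
    labels[rho <= 0.56] = TISSUES["WM"]

    # lateral ventricles: two CSF ellipsoids inside the WM core
    for side in (-1.0, 1.0):
        cx, cy, cz = side * 0.16 * j(), 0.05 * j(), 0.05 * j()
        vr = ((x - cx) / (0.12 * j())) ** 2 + ((y - cy) / (0.32 * j())) ** 2 \
            + ((z - cz) / (0.17 * j())) ** 2
        labels[vr <= 1.0] = TISSUES["CSF"]

    # two anterior eye spheres, partly outside the skull
    for side in (-1.0, 1.0):
        cx, cy, cz = side * 0.32 * j(), -0.86 * j(0.03), -0.15 * j()
        er = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        labels[er <= (0.11 * j()) ** 2] = TISSUES["eyes"]

    if spec.lesion:
        cx, cy, cz = 0.25 * j(0.2), 0.15 * j(0.4), 0.12 * j(0.3)
        lr = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        inside_brain = (labels == TISSUES["WM"]) | (labels == TISSUES["GM"])
        labels[(lr <= (0.22 * j(0.1)) ** 2) & inside_brain] = TISSUES["lesion"]

    return TissueMap(labels)


def _lesion_rim(tmap: TissueMap) -> np.ndarray:
    lesion = tmap.mask("lesion")
    if not lesion.any():
        return lesion
    core = ndimage.binary_erosion(lesion, iterations=2)
    return lesion & ~core


def _ghost(image: np.ndarray, head: np.ndarray, amplitude: float = 0.14) -> np.ndarray:
    """Nyquist-style ghosting: a half-FOV shifted copy of the head silhouette,
    visible only outside the head."""
    ghost = np.roll(image * head, image.shape[1] // 2, axis=1)
    return image + amplitude * ghost * (~head)


def _render_static(spec: PhantomSpec, tmap: TissueMap, table: dict[str, float],
                   scale: dict[str, float] | None = None) -> np.ndarray:
    img = np.zeros(tmap.labels.shape, dtype=np.float32)
    for tissue, code in TISSUES.items():
        mean = table.get(tissue)
        if mean is None:
            continue
        if scale and tissue in scale:
            mean = mean * scale[tissue]
        img[tmap.labels == code] = mean
    if "lesion_rim" in table:
        img[_lesion_rim(tmap)] = table["lesion_rim"]
    return img


def _render_derived(spec: PhantomSpec, tmap: TissueMap) -> np.ndarray:
    """Smooth low-frequency parametric map over the brain mask (ADC/CBV-like)."""
    x, y, z = _normalized_coords(tmap.labels.shape)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    ph = rng.uniform(0, 2 * math.pi, size=3)
    f = 0.45 + 0.25 * np.sin(2.1 * x + ph[0]) * np.cos(1.7 * y + ph[1]) \
        + 0.15 * np.sin(1.3 * z + ph[2])
    brain = np.isin(tmap.labels, [TISSUES[t] for t in ("CSF", "GM", "WM", "lesion")])
    img = np.zeros(tmap.labels.shape, dtype=np.float32)
    img[brain] = np.clip(f, 0.05, 1.0)[brain].astype(np.float32)
    img[tmap.mask("skull")] = 0.05
    img[tmap.mask("eyes")] = 0.30
    return img


def render_scan(spec: PhantomSpec, tmap: TissueMap,
                contrast_table: dict[str, dict[str, float]] | None = None) -> Volume:
    """Assign class-specific tissue intensities (plus noise and artifacts).

    Returns a rank-3 volume, or rank-4 when ``spec.n_temporal > 1`` (DWI
    b-value attenuation or a DSC bolus passage dip across time points).
    """
    if tuple(tmap.labels.shape) != tuple(spec.grid_shape):
        raise ValueError("tissue map shape does not match spec grid_shape")
    table = (contrast_table or CONTRAST_TABLE)[spec.scan_type]

    frames: list[np.ndarray] = []
    for t in range(spec.n_temporal):
        if spec.scan_type == "derived":
            img = _render_derived(spec, tmap)
        elif spec.scan_type == "DWI":
            # per-b-value attenuation: CSF decays much faster than tissue
            scale = {"CSF": math.exp(-1.2 * t), "GM": math.exp(-0.35 * t),
                     "WM": math.exp(-0.35 * t), "lesion": math.exp(-0.2 * t)}
            img = _render_static(spec, tmap, table, scale)
        elif spec.scan_type == "PWI-DSC" and spec.n_temporal > 1:
            # mid-series signal dip as the contrast bolus passes
            t0 = (spec.n_temporal - 1) / 2.0
            dip = 1.0 - 0.35 * math.exp(-((t - t0) ** 2) / (2 * 1.5 ** 2))
            scale = {"GM": dip, "WM": dip, "CSF": 0.6 + 0.4 * dip}
            img = _render_static(spec, tmap, table, scale)
        else:
            img = _render_static(spec, tmap, table)
        if spec.ghosting_enabled:
            img = _ghost(img, tmap.head_mask)
        frames.append(img)

    vox = frames[0] if spec.n_temporal == 1 else np.stack(frames, axis=-1)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))
        vox = vox + rng.normal(0.0, spec.noise_sd, size=vox.shape)
        vox = np.clip(vox, 0.0, None)
    affine = np.diag([*spec.spacing_mm, 1.0])
    return Volume(vox.astype(np.float32), affine)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

# series-description synonym pools.  Misleading entries are drawn from the
# *wrong* class's pool at a configurable rate, emulating free-text protocol
# names that do not reflect the acquired contrast.
DESCRIPTION_POOL: dict[str, list[str]] = {
    "T1w": ["T1", "AX T1", "t1_se_tra", "3D T1 MPRAGE", "T1W_SE", "sag spgr"],
    "T1wC": ["T1 POST GD", "AX T1 +C", "t1_mprage_post", "T1 GAD", "t1_se_gd"],
    "T2w": ["T2", "AX T2", "t2_tse_tra", "T2W_TSE", "T2/PD dual"],
    "PDw": ["PD", "pd_tse_tra", "proton density", "T2/PD dual", "dual echo"],
    "T2w-FLAIR": ["FLAIR", "AX FLAIR", "t2_flair_tra", "dark fluid", "flair 3mm"],
    "DWI": ["DWI", "ep2d_diff_tra", "TRACEW", "dwi b1000", "ax diffusion"],
    "PWI-DSC": ["PERFUSION", "ep2d_perf", "DSC", "dyn susc contrast", "perf bolus"],
    "derived": ["ADC", "adc map", "rCBV", "FA map", "ep2d_diff_ADC"],
}

# plausible sequence timing per class (TR, TE in ms); derived maps carry none
_TIMING = {
    "T1w": (550.0, 14.0), "T1wC": (550.0, 14.0), "T2w": (4200.0, 100.0),
    "PDw": (3000.0, 15.0), "T2w-FLAIR": (9000.0, 120.0), "DWI": (5200.0, 85.0),
    "PWI-DSC": (1500.0, 30.0), "derived": (None, None),
}

_GRID_CHOICES = [(64, 64, 36), (72, 72, 32), (64, 72, 40), (80, 80, 32)]
_SPACING_CHOICES = [(3.0, 3.0, 4.0), (3.5, 3.5, 4.5), (3.0, 3.5, 5.0)]


def _class_counts(total: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of ``total`` scans to classes."""
    raw = {c: total * mix.get(c, 0.0) for c in CLASS_LABELS}
    counts = {c: int(math.floor(v)) for c, v in raw.items()}
    leftover = total - sum(counts.values())
    order = sorted(CLASS_LABELS, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:leftover]:
        counts[c] += 1
    return counts


def generate_dataset(
    n_subjects: int,
    class_mix: Optional[dict[str, float]] = None,
    seed: int = 0,
    dest: os.PathLike | str = ".",
    scans_per_subject: int = 1,
    noise_sd: float = 0.03,
    fourd_fraction: float = 0.2,
    misleading_fraction: float = 0.2,
) -> pd.DataFrame:
    """Write an unsorted phantom DICOM tree and return its ground-truth manifest.

    The tree emulates an unstructured clinical export: randomized folder
    names, inconsistent free-text series descriptions (a fraction of them
    actively misleading), mixed acquisition orientations and grid
    geometries, and a fraction of DWI / PWI-DSC series stored 4-D.  The
    manifest (one row per scan) is also written to ``dest/manifest.tsv``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if scans_per_subject < 1:
        raise ValueError("scans_per_subject must be >= 1")
    mix = class_mix or {c: 1.0 / len(CLASS_LABELS) for c in CLASS_LABELS}
    s = sum(mix.values())
    if abs(s - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1 (got {s})")

    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))

    total = n_subjects * scans_per_subject
    counts = _class_counts(total, mix)
    assignment = [c for c in CLASS_LABELS for _ in range(counts[c])]
    rng.shuffle(assignment)

    rows = []
    scan_idx = 0
    for si in range(n_subjects):
        subject = f"{si + 1:03d}"
        session = "001"
        for _ in range(scans_per_subject):
            scan_type = assignment[scan_idx]
            scan_idx += 1
            if scan_type in ("DWI", "PWI-DSC", "derived"):
                orientation = str(rng.choice(["axial", "coronal", "sagittal"],
                                             p=[0.8, 0.1, 0.1]))
            else:
                orientation = str(rng.choice(list(ORIENTATIONS),
                                             p=[0.5, 0.15, 0.15, 0.2]))
            n_temporal = 1
            if scan_type in FOUR_D_CAPABLE and rng.random() < fourd_fraction:
                n_temporal = 3 if scan_type == "DWI" else 6

            spec = PhantomSpec(
                scan_type=scan_type,
                grid_shape=_GRID_CHOICES[int(rng.integers(len(_GRID_CHOICES)))],
                spacing_mm=_SPACING_CHOICES[int(rng.integers(len(_SPACING_CHOICES)))],
                orientation=orientation,
                n_temporal=n_temporal,
                noise_sd=noise_sd,
                lesion=(scan_type == "T1wC") or bool(rng.random() < 0.3),
                seed=int(rng.integers(2 ** 31 - 1)),
            )
            vol = render_scan(spec, generate_tissue_map(spec))

            desc_class = scan_type
            if rng.random() < misleading_fraction:
                others = [c for c in CLASS_LABELS if c != scan_type]
                desc_class = others[int(rng.integers(len(others)))]
            description = DESCRIPTION_POOL[desc_class][
                int(rng.integers(len(DESCRIPTION_POOL[desc_class])))]

            tr, te = _TIMING[scan_type]
            jitter = lambda v: None if v is None else float(v * rng.uniform(0.9, 1.1))
            image_type = ["ORIGINAL", "PRIMARY"]
            if scan_type == "derived":
                image_type = ["DERIVED", "SECONDARY", "ADC"]
            meta = SeriesMetadata(
                series_uid=f"2.25.{seed + 1}.{scan_idx}",
                series_description=description,
                study_description="BRAIN MRI",
                image_type=image_type,
                repetition_time_ms=jitter(tr),
                echo_time_ms=jitter(te),
                acquisition_type="3D" if orientation == "threeD" else "2D",
                subject_id=subject,
                session_id=f"2.25.{seed + 1}.{si + 1}.1",
            )
            series_dir = dest / f"{rng.integers(2**32):08x}" / f"{rng.integers(2**32):08x}"
            write_dicom_series(vol, meta, series_dir, orientation=orientation)
            rows.append({
                "path": str(series_dir),
                "subject": subject,
                "session": session,
                "scan_type": scan_type,
                "orientation": orientation,
                "is_4d": int(n_temporal > 1),
            })

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(dest / "manifest.tsv", sep="\t", index=False)
    return manifest
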