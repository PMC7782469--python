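"""End-to-end orchestration: directory tree -> predictions -> sorted dataset.

Thin glue over the IO, preprocessing, classifier and aggregation modules;
the CLI and the test-bench both drive the pipeline through these
functions, so behaviour is identical from either entry point.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from . import dicom_io, preprocess
from .aggregate import classify_orientation, majority_vote, predictions_to_frame
from .classifier.model import SliceCNN
from .labels import class_index
from .sorter import DEFAULT_RULES, heuristic_classify
from .types import ScanPrediction, SeriesMetadata, SliceSample

logger = logging.getLogger(__name__)


def iter_preprocessed(root: Path | str, manifest: Optional[pd.DataFrame] = None
                      ) -> Iterator[tuple[str, SeriesMetadata, list[SliceSample]]]:
    """Preprocess every DICOM series under ``root`` (or listed in a manifest).

    Yields ``(scan_id, metadata, 25 slice samples)`` per series.  With a
    ground-truth manifest (column ``path`` holding series directories) the
    scan_id is the manifest path and ``true_class`` is attached; without
    one, series are discovered by walking the tree and keyed by series UID.
    """
    if manifest is not None:
        for row in manifest.itertuples(index=False):
            series_dir = Path(row.path)
            files = sorted(p for p in series_dir.rglob("*") if p.is_file())
            vol = dicom_io.assemble_volume(files)
            true_class = getattr(row, "scan_type", None)
            samples = preprocess.preprocess_scan(vol, scan_id=str(row.path),
                                                 true_class=true_class)
            yield str(row.path), vol.metadata, samples
    else:
        for uid, files in dicom_io.scan_directory(root).items():
            vol = dicom_io.assemble_volume(files)
            samples = preprocess.preprocess_scan(vol, scan_id=uid)
            yield uid, vol.metadata, samples


def build_training_arrays(scans: Sequence[tuple[str, SeriesMetadata, list[SliceSample]]],
                          model: SliceCNN
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Stack slice samples into training matrices at the model's working
    resolution (pooled once, up front, to bound memory)."""
    xs, fds, ys, ids = [], [], [], []
    for scan_id, _meta, samples in scans:
        pixels = np.stack([s.pixels for s in samples])[:, np.newaxis, :, :]
        xs.append(model.pool_input(pixels))
        fds.extend(s.four_d_label for s in samples)
        if samples[0].true_class is None:
            raise ValueError(f"scan {scan_id} has no true_class label")
        ys.extend(class_index(s.true_class) for s in samples)
        ids.extend([scan_id] * len(samples))
    return (np.concatenate(xs), np.asarray(fds, dtype=np.float32),
            np.asarray(ys, dtype=int), ids)


def predict_scan(model: SliceCNN, scan_id: str, meta: Optional[SeriesMetadata],
                 samples: Sequence[SliceSample]) -> tuple[ScanPrediction, np.ndarray]:
    """Slice probabilities + majority vote + orientation for one scan."""
    probs = model.predict_scan_probs(samples)
    pred = majority_vote(probs, scan_id=scan_id)
    if meta is not None:
        try:
            pred.orientation = classify_orientation(meta)
        except ValueError:
            logger.warning("scan %s: orientation undetermined", scan_id)
            pred.orientation = None
    return pred, probs


def predict_tree(root: Path | str, model: SliceCNN,
                 manifest: Optional[pd.DataFrame] = None
                 ) -> tuple[list[ScanPrediction], dict[str, np.ndarray]]:
    """Classify every series under ``root``; returns scan predictions and the
    per-scan slice probability matrices (for per-slice evaluation)."""
    predictions = []
    slice_probs: dict[str, np.ndarray] = {}
    for scan_id, meta, samples in iter_preprocessed(root, manifest):
        pred, probs = predict_scan(model, scan_id, meta, samples)
        predictions.append(pred)
        slice_probs[scan_id] = probs
    return predictions, slice_probs


def heuristic_predict_tree(root: Path | str, manifest: Optional[pd.DataFrame] = None,
                           rules=DEFAULT_RULES) -> dict[str, str]:
    """Metadata-baseline classification of every series (scan_id -> label)."""
    out: dict[str, str] = {}
    if manifest is not None:
        for row in manifest.itertuples(index=False):
            files = sorted(p for p in Path(row.path).rglob("*") if p.is_file())
            meta = dicom_io.extract_metadata(files)
            out[str(row.path)] = heuristic_classify(meta, rules)
    else:
        for uid, files in dicom_io.scan_directory(root).items():
            out[uid] = heuristic_classify(dicom_io.extract_metadata(files), rules)
    return out


def write_predictions(predictions: Sequence[ScanPrediction], path: Path | str) -> Path:
    path = Path(path)
    predictions_to_frame(predictions).to_csv(path, sep="\t", index=False)
    return path
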