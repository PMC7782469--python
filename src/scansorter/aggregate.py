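"""Scan-level decisions: majority vote, orientation from direction cosines,
and evaluation metrics.

A scan's class is the most frequent per-slice argmax over its 25 slices.
Ties (never addressed by a 25-slice vote alone, but possible) are broken
deterministically: highest mean probability among the tied classes, then
lowest class index; ``tie_broken`` records when that chain fired.

Spatial orientation comes from the DICOM direction cosines: the slice
normal is the cross product of the row and column vectors and its largest
absolute component decides axial (z), coronal (y) or sagittal (x).  The
cosines of a 3-D acquisition look like those of any 2-D stack, so 3-D is
detected from MRAcquisitionType (0018,0023) instead.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .labels import CLASS_LABELS, N_CLASSES
from .types import ScanPrediction, SeriesMetadata, validate_probabilities

N_VOTES = 25


def majority_vote(slice_probs: np.ndarray | Sequence[Sequence[float]],
                  scan_id: str = "") -> ScanPrediction:
    """Aggregate exactly 25 per-slice probability vectors into a scan label."""
    probs = np.asarray(slice_probs, dtype=float)
    if probs.shape != (N_VOTES, N_CLASSES):
        raise ValueError(f"expected {N_VOTES}x{N_CLASSES} probabilities, got {probs.shape}")
    validate_probabilities(probs)

    votes = probs.argmax(axis=1)
    counts = np.bincount(votes, minlength=N_CLASSES)
    mean_probs = probs.mean(axis=0)

    top = counts.max()
    tied = np.flatnonzero(counts == top)
    tie_broken = len(tied) > 1
    if tie_broken:
        # highest mean probability among tied classes; argmax takes the
        # lowest index on an exact tie, completing the deterministic chain
        winner = int(tied[np.argmax(mean_probs[tied])])
    else:
        winner = int(tied[0])
    return ScanPrediction(
        scan_id=scan_id,
        predicted_class=CLASS_LABELS[winner],
        vote_counts=counts,
        mean_probabilities=mean_probs,
        tie_broken=tie_broken,
    )


def classify_orientation(meta: SeriesMetadata) -> str:
    """axial / coronal / sagittal / threeD from the series metadata."""
    if meta.acquisition_type is not None and meta.acquisition_type.upper() == "3D":
        return "threeD"
    if meta.direction_cosines is None:
        raise ValueError(
            "orientation undetermined: series has neither direction cosines "
            "(0020,0037) nor an MRAcquisitionType of '3D'"
        )
    dc = np.asarray(meta.direction_cosines, dtype=float)
    normal = np.cross(dc[:3], dc[3:])
    axis = int(np.argmax(np.abs(normal)))
    return ("sagittal", "coronal", "axial")[axis]


def evaluate(predictions: Sequence[ScanPrediction],
             truth: pd.DataFrame | dict[str, str]) -> dict:
    """Overall accuracy, per-class accuracy and the 8x8 confusion matrix.

    ``truth`` maps scan_id to true class (a dict, or a DataFrame with
    ``scan_id``/``scan_type`` columns).  Rows of the confusion matrix are
    truth classes, columns are predictions.
    """
    if isinstance(truth, pd.DataFrame):
        truth = dict(zip(truth["scan_id"].astype(str), truth["scan_type"]))
    missing = [p.scan_id for p in predictions if p.scan_id not in truth]
    if missing:
        raise ValueError(f"no ground truth for scan_ids: {missing}")

    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for p in predictions:
        t = CLASS_LABELS.index(truth[p.scan_id])
        c = CLASS_LABELS.index(p.predicted_class)
        confusion[t, c] += 1
    total = int(confusion.sum())
    overall = float(np.trace(confusion) / total) if total else float("nan")
    per_class = {}
    for i, label in enumerate(CLASS_LABELS):
        row = confusion[i].sum()
        per_class[label] = float(confusion[i, i] / row) if row else None
    return {
        "n_scans": total,
        "overall_accuracy": overall,
        "per_class_accuracy": per_class,
        "confusion_matrix": confusion.tolist(),
        "class_labels": list(CLASS_LABELS),
    }


def per_slice_accuracy(slice_probs_by_scan: dict[str, np.ndarray],
                       truth: dict[str, str]) -> float:
    """Accuracy of the raw per-slice argmax, before the majority vote."""
    correct = 0
    total = 0
    for scan_id, probs in slice_probs_by_scan.items():
        t = CLASS_LABELS.index(truth[scan_id])
        votes = np.asarray(probs).argmax(axis=1)
        correct += int((votes == t).sum())
        total += len(votes)
    return correct / total if total else float("nan")


def predictions_to_frame(predictions: Sequence[ScanPrediction]) -> pd.DataFrame:
    """Tabular form of scan predictions (votes, mean probabilities, orientation)."""
    rows = []
    for p in predictions:
        row = {"scan_id": p.scan_id, "predicted_class": p.predicted_class,
               "orientation": p.orientation or "", "tie_broken": int(p.tie_broken)}
        for i, label in enumerate(CLASS_LABELS):
            row[f"votes_{label}"] = int(p.vote_counts[i])
        for i, label in enumerate(CLASS_LABELS):
            row[f"prob_{label}"] = float(p.mean_probabilities[i])
        rows.append(row)
    return pd.DataFrame.from_records(rows)
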