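"""Desk-scale synthetic study: the package's end-to-end self-evaluation.

Generates a labelled phantom dataset, trains the reduced slice CNN on a
subject-level 75% split, and evaluates scan-level accuracy (majority
vote), per-slice accuracy, orientation accuracy and the metadata-heuristic
baseline on the held-out 25%.  Study conditions follow the synthetic-data
defaults: eight classes in equal proportion, mixed acquisition
orientations, 20% of DWI/PWI-DSC series stored 4-D, additive noise with
sd 0.03 of the intensity range, and 20% misleading series descriptions.

Problem sizes (400 scans, 64x64 working resolution, at most 12 epochs)
were chosen so the whole study runs on a single CPU core in minutes while
leaving the eight classes' learnability non-trivial.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import pipeline
from .aggregate import evaluate, per_slice_accuracy
from .classifier.model import SliceCNN, reduced_config
from .classifier.training import TrainConfig, train
from .labels import CLASS_LABELS
from .phantoms import generate_dataset

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    overall_accuracy: float
    per_class_accuracy: dict[str, Optional[float]]
    confusion_matrix: list[list[int]]
    per_slice_accuracy: float
    heuristic_accuracy: float
    orientation_accuracy: float
    n_scans: int
    n_train_scans: int
    n_test_scans: int
    n_epochs: int
    final_loss: float
    history: pd.DataFrame
    model: SliceCNN
    manifest: pd.DataFrame
    test_manifest: pd.DataFrame
    predictions: list
    data_dir: Path


def split_scans(manifest: pd.DataFrame, test_fraction: float,
                seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified (per scan type) train/test split of manifest rows."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    test_idx: list[int] = []
    for label in CLASS_LABELS:
        idx = manifest.index[manifest["scan_type"] == label].to_numpy()
        rng.shuffle(idx)
        n_test = max(1, int(round(len(idx) * test_fraction))) if len(idx) else 0
        test_idx.extend(idx[:n_test])
    test_mask = manifest.index.isin(test_idx)
    return manifest[~test_mask].copy(), manifest[test_mask].copy()


def run_study(seed: int = 0, n_subjects: int = 50, scans_per_subject: int = 8,
              test_fraction: float = 0.25, max_epochs: int = 12,
              noise_sd: float = 0.03, misleading_fraction: float = 0.2,
              fourd_fraction: float = 0.2,
              data_dir: Optional[Path] = None) -> StudyResult:
    """Run the full synthetic study; see the module docstring for conditions."""
    if data_dir is None:
        data_dir = Path(tempfile.mkdtemp(prefix="scansorter-study-"))
    data_dir = Path(data_dir)

    logger.info("generating %d phantom scans", n_subjects * scans_per_subject)
    manifest = generate_dataset(
        n_subjects=n_subjects, scans_per_subject=scans_per_subject, seed=seed,
        dest=data_dir, noise_sd=noise_sd, fourd_fraction=fourd_fraction,
        misleading_fraction=misleading_fraction,
    )
    train_man, test_man = split_scans(manifest, test_fraction, seed)

    model = SliceCNN(reduced_config(), seed=seed)
    logger.info("preprocessing %d training scans", len(train_man))
    train_scans = pipeline.iter_preprocessed(data_dir, train_man)
    X, four_d, y, _ids = pipeline.build_training_arrays(list(train_scans), model)

    cfg = TrainConfig(seed=seed, max_epochs=max_epochs)
    logger.info("training on %d slice samples", len(y))
    history = train(model, X, four_d, y, cfg, pre_pooled=True)
    del X

    logger.info("evaluating on %d held-out scans", len(test_man))
    predictions = []
    slice_probs: dict[str, np.ndarray] = {}
    orient_ok = 0
    for scan_id, meta, samples in pipeline.iter_preprocessed(data_dir, test_man):
        pred, probs = pipeline.predict_scan(model, scan_id, meta, samples)
        predictions.append(pred)
        slice_probs[scan_id] = probs
        truth_orient = test_man.loc[test_man["path"] == scan_id, "orientation"].iloc[0]
        orient_ok += int(pred.orientation == truth_orient)

    truth = dict(zip(test_man["path"], test_man["scan_type"]))
    metrics = evaluate(predictions, truth)
    slice_acc = per_slice_accuracy(slice_probs, truth)

    heur = pipeline.heuristic_predict_tree(data_dir, test_man)
    heur_acc = float(np.mean([heur[sid] == truth[sid] for sid in truth]))

    return StudyResult(
        overall_accuracy=metrics["overall_accuracy"],
        per_class_accuracy=metrics["per_class_accuracy"],
        confusion_matrix=metrics["confusion_matrix"],
        per_slice_accuracy=slice_acc,
        heuristic_accuracy=heur_acc,
        orientation_accuracy=orient_ok / len(test_man),
        n_scans=len(manifest),
        n_train_scans=len(train_man),
        n_test_scans=len(test_man),
        n_epochs=len(history),
        final_loss=float(history["loss"].iloc[-1]),
        history=history,
        model=model,
        manifest=manifest,
        test_manifest=test_man,
        predictions=predictions,
        data_dir=data_dir,
    )
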