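"""Majority vote, orientation from direction cosines, evaluation metrics."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from scansorter.aggregate import (classify_orientation, evaluate,
                                  majority_vote, per_slice_accuracy)
from scansorter.labels import CLASS_LABELS
from scansorter.types import ScanPrediction, SeriesMetadata


def _probs_from_votes(votes, peak=0.9):
    """25x8 probability rows whose argmax realizes the given vote list."""
    probs = np.full((25, 8), (1 - peak) / 7)
    for i, v in enumerate(votes):
        probs[i, v] = peak
    return probs


def brute_force_vote(probs):
    """Independent tally: count argmaxes, resolve ties by mean probability
    then class index, by explicit enumeration."""
    votes = [int(np.argmax(row)) for row in probs]
    counts = [votes.count(c) for c in range(8)]
    top = max(counts)
    tied = [c for c in range(8) if counts[c] == top]
    mean = probs.mean(axis=0)
    best = sorted(tied, key=lambda c: (-mean[c], c))[0]
    return best, counts, len(tied) > 1


class TestMajorityVote:
    def test_strict_majority(self):
        votes = [0] * 13 + [2] * 12
        pred = majority_vote(_probs_from_votes(votes))
        assert pred.predicted_class == "T1w"
        assert not pred.tie_broken

    def test_unanimous(self):
        pred = majority_vote(_probs_from_votes([5] * 25))
        assert pred.predicted_class == "DWI"
        assert pred.vote_counts[5] == 25 and not pred.tie_broken

    def test_tie_broken_by_mean_probability(self):
        votes = [0] * 10 + [2] * 10 + [3] * 5
        probs = _probs_from_votes(votes)
        row = np.full(8, 0.01 / 7)
        row[2] = 0.99
        probs[votes.index(2)] = row  # push T2w's mean above T1w's
        pred = majority_vote(probs)
        assert pred.predicted_class == "T2w"
        assert pred.tie_broken

    def test_wrong_count_rejected(self):
        with pytest.raises(ValueError, match="25"):
            majority_vote(np.full((24, 8), 1 / 8))

    def test_vote_conservation_and_oracle_equivalence(self):
        """10,000 random probability sets (forced ties included): result and
        tally match brute-force counting exactly."""
        rng = np.random.default_rng(123)
        for trial in range(10_000):
            raw = rng.dirichlet(np.full(8, 0.3), size=25)
            if trial % 5 == 0:  # force frequent argmax ties
                raw = np.round(raw, 1)
                raw = raw / raw.sum(axis=1, keepdims=True)
            pred = majority_vote(raw)
            exp_class, exp_counts, exp_tie = brute_force_vote(raw)
            assert pred.predicted_class == CLASS_LABELS[exp_class]
            assert pred.vote_counts.tolist() == exp_counts
            assert int(pred.vote_counts.sum()) == 25
            assert pred.tie_broken == exp_tie


def _meta(cosines=None, acq=None):
    return SeriesMetadata(series_uid="u", direction_cosines=cosines,
                          acquisition_type=acq)


class TestClassifyOrientation:
    def test_axial_identity(self):
        assert classify_orientation(_meta((1, 0, 0, 0, 1, 0))) == "axial"

    def test_sagittal(self):
        assert classify_orientation(_meta((0, 1, 0, 0, 0, -1))) == "sagittal"

    def test_oblique_coronal(self):
        # row/col chosen so the normal ~ (0.48, 0.64, 0.60) -> largest |y|... not:
        # normal here is dominated by its y component -> coronal
        row = np.array([0.8, -0.6, 0.0])
        col = np.array([0.0, 0.0, -1.0])
        cos = tuple(row) + tuple(col)
        normal = np.cross(row, col)
        assert np.argmax(np.abs(normal)) == 1
        assert classify_orientation(_meta(cos)) == "coronal"

    def test_acquisition_type_3d_wins(self):
        assert classify_orientation(_meta((1, 0, 0, 0, 1, 0), acq="3D")) == "threeD"

    def test_undetermined_errors(self):
        with pytest.raises(ValueError, match="undetermined"):
            classify_orientation(_meta())

    def test_all_axis_aligned_configurations_match_cross_product(self):
        """All 48 signed axis-aligned row/column pairs agree with an
        exhaustive cross-product + argmax computation."""
        axes = [np.array(v) for v in ([1, 0, 0], [0, 1, 0], [0, 0, 1])]
        checked = 0
        for i, j in itertools.permutations(range(3), 2):
            for si, sj in itertools.product((1, -1), repeat=2):
                row, col = si * axes[i], sj * axes[j]
                normal = np.cross(row, col)
                expected = ("sagittal", "coronal", "axial")[
                    int(np.argmax(np.abs(normal)))]
                got = classify_orientation(_meta(tuple(row) + tuple(col)))
                assert got == expected
                checked += 1
        assert checked == 24  # 24 proper configurations x 2 signs of normal = 48 normals
        # the mirrored normals are covered by swapping row/col:
        for i, j in itertools.permutations(range(3), 2):
            for si, sj in itertools.product((1, -1), repeat=2):
                row, col = si * axes[j], sj * axes[i]
                normal = np.cross(row, col)
                expected = ("sagittal", "coronal", "axial")[
                    int(np.argmax(np.abs(normal)))]
                assert classify_orientation(_meta(tuple(row) + tuple(col))) == expected

    def test_random_oblique_rotations_match_oracle(self):
        """1000 random rotations: classification equals cross-product argmax."""
        from scipy.stats import special_ortho_group
        rng = np.random.default_rng(7)
        for _ in range(1000):
            R = special_ortho_group.rvs(3, random_state=rng)
            row, col = R[:, 0], R[:, 1]
            normal = np.cross(row, col)
            expected = ("sagittal", "coronal", "axial")[int(np.argmax(np.abs(normal)))]
            assert classify_orientation(_meta(tuple(row) + tuple(col))) == expected


def _pred(scan_id, label):
    counts = np.zeros(8, int)
    counts[CLASS_LABELS.index(label)] = 25
    probs = np.zeros(8)
    probs[CLASS_LABELS.index(label)] = 1.0
    return ScanPrediction(scan_id, label, counts, probs)


class TestEvaluate:
    def test_all_correct_diagonal(self):
        preds = [_pred(f"s{i}", CLASS_LABELS[i % 8]) for i in range(16)]
        truth = {f"s{i}": CLASS_LABELS[i % 8] for i in range(16)}
        m = evaluate(preds, truth)
        assert m["overall_accuracy"] == 1.0
        cm = np.array(m["confusion_matrix"])
        assert cm.sum() == np.trace(cm) == 16

    def test_partial_accuracy_counts(self):
        truth = {f"a{i}": "T1w" for i in range(5)}
        truth.update({f"b{i}": "T2w" for i in range(5)})
        preds = [_pred(f"a{i}", "T1w") for i in range(5)]
        preds += [_pred(f"b{i}", "T2w") for i in range(3)]
        preds += [_pred(f"b{i}", "T1w") for i in range(3, 5)]
        m = evaluate(preds, truth)
        assert m["overall_accuracy"] == pytest.approx(0.8)
        assert m["per_class_accuracy"]["T1w"] == 1.0
        assert m["per_class_accuracy"]["T2w"] == pytest.approx(0.6)
        assert m["per_class_accuracy"]["DWI"] is None  # no truth scans

    def test_missing_truth_listed(self):
        with pytest.raises(ValueError, match="s1"):
            evaluate([_pred("s1", "T1w")], {})

    def test_row_sums_equal_truth_counts(self):
        rng = np.random.default_rng(9)
        truth = {f"s{i}": CLASS_LABELS[int(rng.integers(8))] for i in range(40)}
        preds = [_pred(k, CLASS_LABELS[int(rng.integers(8))]) for k in truth]
        cm = np.array(evaluate(preds, truth)["confusion_matrix"])
        for i, label in enumerate(CLASS_LABELS):
            assert cm[i].sum() == sum(v == label for v in truth.values())

    def test_per_slice_accuracy_definition(self):
        probs = np.zeros((25, 8))
        probs[:20, 0] = 1.0   # 20 slices say T1w
        probs[20:, 2] = 1.0   # 5 slices say T2w
        acc = per_slice_accuracy({"s": probs}, {"s": "T1w"})
        assert acc == pytest.approx(20 / 25)
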