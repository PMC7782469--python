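"""Sort planning, execution and the metadata-heuristic baseline."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from scansorter.labels import CLASS_LABELS
from scansorter.sorter import (BIDS_NAME_RE, DEFAULT_RULES, execute_plan,
                               heuristic_classify, plan_bids, plan_custom,
                               rules_from_json, rules_to_json)
from scansorter.types import ScanPrediction, SeriesMetadata


def _pred(scan_id, label, orientation="axial"):
    counts = np.zeros(8, int)
    counts[CLASS_LABELS.index(label)] = 25
    probs = np.zeros(8)
    probs[CLASS_LABELS.index(label)] = 1.0
    return ScanPrediction(scan_id, label, counts, probs, orientation=orientation)


def _manifest(rows):
    return pd.DataFrame(rows, columns=["scan_id", "path", "subject", "session"])


@pytest.fixture()
def nifti_sources(tmp_path, t1w_volume):
    from scansorter.dicom_io import write_nifti
    paths = {}
    for name in ("s1", "s2", "s3"):
        paths[name] = str(write_nifti(t1w_volume, tmp_path / f"{name}.nii.gz"))
    return paths


class TestPlanBids:
    def test_contrast_enhanced_naming(self, nifti_sources, tmp_path):
        man = _manifest([{"scan_id": "s1", "path": nifti_sources["s1"],
                          "subject": "3", "session": "1"}])
        plan = plan_bids([_pred("s1", "T1wC")], man, tmp_path / "bids",
                         source_column="path")
        dest = plan.entries[0].destination
        assert dest == (tmp_path / "bids" / "sub-003" / "ses-001" / "anat"
                        / "sub-003_ses-001_ce-gd_T1w.nii.gz")

    def test_duplicates_get_run_indices(self, nifti_sources, tmp_path):
        man = _manifest([
            {"scan_id": "s1", "path": nifti_sources["s1"], "subject": "1", "session": "1"},
            {"scan_id": "s2", "path": nifti_sources["s2"], "subject": "1", "session": "1"},
        ])
        plan = plan_bids([_pred("s1", "T2w"), _pred("s2", "T2w")], man,
                         tmp_path / "bids", source_column="path")
        names = sorted(e.destination.name for e in plan.entries)
        assert names == ["sub-001_ses-001_run-01_T2w.nii.gz",
                         "sub-001_ses-001_run-02_T2w.nii.gz"]

    def test_all_names_match_bids_grammar(self, nifti_sources, tmp_path):
        man = _manifest([
            {"scan_id": f"s{i+1}", "path": nifti_sources[f"s{i+1}"],
             "subject": str(i + 1), "session": "1"} for i in range(3)])
        preds = [_pred("s1", "T1w"), _pred("s2", "T2w-FLAIR"), _pred("s3", "DWI")]
        plan = plan_bids(preds, man, tmp_path / "bids", source_column="path")
        for e in plan.entries:
            assert BIDS_NAME_RE.match(e.destination.name), e.destination.name

    def test_missing_subject_rejected(self, nifti_sources, tmp_path):
        man = _manifest([{"scan_id": "s1", "path": nifti_sources["s1"],
                          "subject": "", "session": "1"}])
        with pytest.raises(ValueError, match="subject"):
            plan_bids([_pred("s1", "T1w")], man, tmp_path / "bids",
                      source_column="path")

    def test_executed_bids_tree(self, nifti_sources, tmp_path):
        man = _manifest([
            {"scan_id": "s1", "path": nifti_sources["s1"], "subject": "1", "session": "1"},
            {"scan_id": "s2", "path": nifti_sources["s2"], "subject": "2", "session": "1"},
        ])
        plan = plan_bids([_pred("s1", "T1w"), _pred("s2", "derived")], man,
                         tmp_path / "bids", source_column="path")
        report = execute_plan(plan, mode="copy")
        assert (tmp_path / "bids" / "dataset_description.json").exists()
        assert (tmp_path / "bids" / "sub-001" / "ses-001" / "anat"
                / "sub-001_ses-001_T1w.nii.gz").exists()
        assert (tmp_path / "bids" / "derivatives" / "scansorter").exists()
        assert set(report["status"]) == {"copied"}


class TestPlanCustom:
    def test_template_paths(self, small_dataset, tmp_path):
        root, manifest = small_dataset
        man = manifest.assign(scan_id=manifest["path"])
        row = man.iloc[0]
        preds = [_pred(row["scan_id"], "T1w", orientation="axial")]
        plan = plan_custom(preds, man, "{subject}/{scan_type}_{orientation}",
                           tmp_path / "out")
        assert all(str(e.destination).startswith(
            str(tmp_path / "out" / row["subject"] / "T1w_axial")) for e in plan.entries)

    def test_unknown_placeholder_named(self, small_dataset, tmp_path):
        root, manifest = small_dataset
        man = manifest.assign(scan_id=manifest["path"])
        with pytest.raises(ValueError, match="flavour"):
            plan_custom([_pred(man.iloc[0]["scan_id"], "T1w")], man,
                        "{subject}/{flavour}", tmp_path / "out")

    def test_collision_without_run_rejected(self, small_dataset, tmp_path):
        root, manifest = small_dataset
        man = manifest.assign(scan_id=manifest["path"],
                              subject="001", session="001")
        preds = [_pred(p, "T1w") for p in man["scan_id"][:2]]
        with pytest.raises(ValueError, match="colliding"):
            plan_custom(preds, man, "{subject}/{scan_type}", tmp_path / "out")

    def test_empty_predictions_empty_plan(self, small_dataset, tmp_path):
        root, manifest = small_dataset
        man = manifest.assign(scan_id=manifest["path"])
        plan = plan_custom([], man, "{subject}/{scan_type}", tmp_path / "out")
        assert plan.entries == []


class TestExecutePlan:
    def _dicom_plan(self, small_dataset, out):
        root, manifest = small_dataset
        man = manifest.assign(scan_id=manifest["path"])
        preds = [_pred(p, t) for p, t in zip(man["scan_id"], man["scan_type"])]
        return plan_custom(preds, man, "{subject}/{scan_type}_{run}", out), man

    def test_dry_run_touches_nothing(self, small_dataset, tmp_path):
        plan, _ = self._dicom_plan(small_dataset, tmp_path / "out")
        report = execute_plan(plan, mode="dry_run")
        assert not (tmp_path / "out").exists()
        assert set(report["status"]) == {"planned"}

    def test_copy_preserves_bytes_and_is_idempotent(self, small_dataset, tmp_path):
        plan, _ = self._dicom_plan(small_dataset, tmp_path / "out")
        first = execute_plan(plan, mode="copy")
        assert set(first["status"]) == {"copied"}
        # byte preservation: SHA-256 of each source equals its destination
        for e in plan.entries:
            src = hashlib.sha256(e.sources[0].read_bytes()).hexdigest()
            dst = hashlib.sha256(e.destination.read_bytes()).hexdigest()
            assert src == dst
        second = execute_plan(plan, mode="copy")
        assert set(second["status"]) == {"skipped"}

    def test_differing_destination_aborts_before_acting(self, small_dataset, tmp_path):
        plan, _ = self._dicom_plan(small_dataset, tmp_path / "out")
        execute_plan(plan, mode="copy")
        victim = plan.entries[0].destination
        victim.write_bytes(b"corrupted")
        sentinel = plan.entries[-1].destination
        sentinel_bytes = sentinel.read_bytes()
        with pytest.raises(FileExistsError, match="different content"):
            execute_plan(plan, mode="copy")
        assert sentinel.read_bytes() == sentinel_bytes

    def test_destination_census(self, small_dataset, tmp_path):
        plan, _ = self._dicom_plan(small_dataset, tmp_path / "out")
        execute_plan(plan, mode="copy")
        copied = [p for p in (tmp_path / "out").rglob("*") if p.is_file()]
        assert len(copied) == len(plan.entries)


class TestHeuristicClassify:
    @pytest.mark.parametrize("desc,te,expected", [
        ("AX T1 POST GD", 14.0, "T1wC"),
        ("T2 PD dual", 15.0, "PDw"),
        ("T2 PD dual", 100.0, "T2w"),
        ("sag spgr", 14.0, "T1w"),
        ("t2_flair_tra", 120.0, "T2w-FLAIR"),
        ("ep2d_diff_tra", 85.0, "DWI"),
        ("dyn susc contrast", 30.0, "PWI-DSC"),
    ])
    def test_rule_table_traces(self, desc, te, expected):
        meta = SeriesMetadata(series_uid="u", series_description=desc,
                              echo_time_ms=te)
        assert heuristic_classify(meta) == expected

    def test_image_type_derived_wins(self):
        meta = SeriesMetadata(series_uid="u", series_description="ep2d_diff_ADC",
                              image_type=["DERIVED", "SECONDARY", "ADC"])
        assert heuristic_classify(meta) == "derived"

    def test_empty_metadata_unknown(self):
        assert heuristic_classify(SeriesMetadata(series_uid="u")) == "unknown"

    def test_rules_json_round_trip(self):
        back = rules_from_json(rules_to_json(DEFAULT_RULES))
        assert [r.output_class for r in back] == [r.output_class for r in DEFAULT_RULES]
        meta = SeriesMetadata(series_uid="u", series_description="AX FLAIR")
        assert heuristic_classify(meta, back) == "T2w-FLAIR"

    def test_duplicate_priorities_rejected(self):
        text = rules_to_json([DEFAULT_RULES[0], DEFAULT_RULES[0]])
        with pytest.raises(ValueError, match="unique"):
            rules_from_json(text)
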