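"""Shared fixtures: small phantom volumes and DICOM trees, generated fresh."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scansorter.phantoms import (PhantomSpec, generate_dataset,
                                 generate_tissue_map, render_scan)
from scansorter.types import SeriesMetadata, Volume


@pytest.fixture(scope="session")
def t1w_volume() -> Volume:
    spec = PhantomSpec("T1w", seed=11)
    return render_scan(spec, generate_tissue_map(spec))


@pytest.fixture(scope="session")
def dwi_4d_volume() -> Volume:
    spec = PhantomSpec("DWI", n_temporal=3, seed=12)
    return render_scan(spec, generate_tissue_map(spec))


@pytest.fixture()
def series_meta() -> SeriesMetadata:
    return SeriesMetadata(series_uid="2.25.77.1", series_description="AX T1",
                          study_description="BRAIN MRI",
                          image_type=["ORIGINAL", "PRIMARY"],
                          repetition_time_ms=550.0, echo_time_ms=14.0,
                          subject_id="001", session_id="2.25.77.0.1")


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory) -> tuple:
    """8 subjects x 1 scan, one of each class; returns (root, manifest)."""
    root = tmp_path_factory.mktemp("phantom-data")
    manifest = generate_dataset(n_subjects=8, seed=3, dest=root)
    return root, manifest
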