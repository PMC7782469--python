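"""Preprocessing chain: 4-D reduction, reorientation, resampling, scaling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scansorter.preprocess import (TARGET_SHAPE, detect_and_reduce_4d,
                                   load_samples, preprocess_scan,
                                   reorient_to_canonical, resample_fixed_grid,
                                   save_samples, split_and_scale)
from scansorter.types import Volume


def _vol(arr, affine=None):
    return Volume(np.asarray(arr, dtype=np.float32),
                  np.eye(4) if affine is None else affine)


class TestDetectAndReduce4D:
    def test_rank4_takes_first_element(self, dwi_4d_volume):
        vol3, label = detect_and_reduce_4d(dwi_4d_volume)
        assert label == 1
        np.testing.assert_array_equal(vol3.voxels, dwi_4d_volume.voxels[..., 0])

    def test_rank3_passes_through(self, t1w_volume):
        vol3, label = detect_and_reduce_4d(t1w_volume)
        assert label == 0
        assert vol3 is t1w_volume

    def test_rank4_with_single_timepoint_still_labelled_4d(self):
        rng = np.random.default_rng(0)
        vol = _vol(rng.normal(size=(8, 8, 4, 1)))
        _, label = detect_and_reduce_4d(vol)
        assert label == 1


class TestReorient:
    def test_canonical_volume_unchanged(self):
        rng = np.random.default_rng(1)
        vol = _vol(rng.normal(size=(8, 9, 10)), np.diag([2.0, 2.0, 3.0, 1.0]))
        out = reorient_to_canonical(vol)
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_single_flip_reversed(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(8, 9, 10)).astype(np.float32)
        affine = np.diag([2.0, 2.0, -3.0, 1.0])  # axis 2 points superior->inferior
        out = reorient_to_canonical(_vol(data, affine))
        np.testing.assert_array_equal(out.voxels, data[:, :, ::-1])
        assert out.axis_orientation == ("R", "A", "S")

    def test_permutation_preserves_voxel_multiset(self):
        """A sagittal-style affine permutes axes; values are rearranged only."""
        rng = np.random.default_rng(3)
        data = rng.normal(size=(10, 8, 9)).astype(np.float32)
        affine = np.zeros((4, 4))
        affine[3, 3] = 1.0
        affine[2, 0] = 1.2   # axis 0 -> superior
        affine[0, 1] = -0.9  # axis 1 -> left
        affine[1, 2] = 0.8   # axis 2 -> anterior
        out = reorient_to_canonical(_vol(data, affine))
        assert out.axis_orientation == ("R", "A", "S")
        assert out.voxels.shape == (8, 9, 10)
        np.testing.assert_array_equal(np.sort(out.voxels.ravel()),
                                      np.sort(data.ravel()))


class TestResampleFixedGrid:
    def test_output_spacing_from_extent(self):
        vol = _vol(np.zeros((128, 128, 50)), np.diag([2.0, 2.0, 1.2, 1.0]))
        out = resample_fixed_grid(vol)
        # oracle: extent/size arithmetic, 128*2/256 and 50*1.2/25
        np.testing.assert_allclose(out.spacing_mm, [1.0, 1.0, 2.4])

    def test_constant_volume_stays_constant(self):
        vol = _vol(np.full((40, 40, 30), 7.25), np.diag([1.0, 2.0, 3.0, 1.0]))
        out = resample_fixed_grid(vol)
        np.testing.assert_allclose(out.voxels, 7.25, rtol=1e-6)

    def test_identity_grid_exact(self):
        rng = np.random.default_rng(4)
        vol = _vol(rng.normal(size=TARGET_SHAPE))
        out = resample_fixed_grid(vol)
        np.testing.assert_allclose(out.voxels, vol.voxels, atol=1e-5)

    def test_physical_extent_conserved(self):
        rng = np.random.default_rng(5)
        vol = _vol(rng.normal(size=(63, 47, 31)), np.diag([1.7, 2.3, 4.1, 1.0]))
        out = resample_fixed_grid(vol)
        np.testing.assert_allclose(out.physical_extent_mm(),
                                   vol.physical_extent_mm(), rtol=1e-6)

    def test_nearest_mode_matches_exhaustive_oracle(self):
        """Order-0 resampling of small integer volumes equals a brute-force
        nearest-neighbour loop exactly."""
        rng = np.random.default_rng(6)
        vol = _vol(rng.integers(0, 100, size=(8, 8, 4)).astype(np.float32))
        out = resample_fixed_grid(vol, order=0)
        expected = np.empty(TARGET_SHAPE, dtype=np.float32)
        for i in range(TARGET_SHAPE[0]):
            for j in range(TARGET_SHAPE[1]):
                for k in range(TARGET_SHAPE[2]):
                    src = []
                    for idx, (n_in, n_out) in zip(
                            (i, j, k), [(8, 256), (8, 256), (4, 25)]):
                        c = (idx + 0.5) * n_in / n_out - 0.5
                        c = min(max(c, 0.0), n_in - 1.0)
                        src.append(min(int(np.floor(c + 0.5)), n_in - 1))
                    expected[i, j, k] = vol.voxels[tuple(src)]
        np.testing.assert_array_equal(out.voxels, expected)

    def test_linear_ramp_resamples_to_analytic_ramp(self):
        """Cubic b-splines reproduce linear functions; away from the edge the
        resampled ramp matches the closed form to 1e-4."""
        n = 40
        ramp = np.broadcast_to(np.arange(n, dtype=np.float32)[:, None, None],
                               (n, 34, 33)).copy()
        out = resample_fixed_grid(_vol(ramp))
        coords = (np.arange(256) + 0.5) * (n / 256) - 0.5
        analytic = np.broadcast_to(coords[:, None, None].astype(np.float32),
                                   (256, 256, 25))
        # edge-clamped spline coefficients perturb the ramp near the ends
        # (decay ~0.27 per input voxel); 8 input voxels in, it is < 1e-4
        interior = slice(56, -56)
        np.testing.assert_allclose(out.voxels[interior], analytic[interior],
                                   atol=1e-4)

    def test_degenerate_spacing_rejected(self):
        with pytest.raises(ValueError):
            _vol(np.zeros((8, 8, 8)), np.diag([0.0, 1.0, 1.0, 1.0]))


class TestSplitAndScale:
    def test_minmax_formula(self):
        vol = np.zeros(TARGET_SHAPE, dtype=np.float32)
        vol[:2, :2, 0] = np.array([[0, 2], [4, 8]])
        samples = split_and_scale(_vol(vol), four_d_label=0, scan_id="s")
        assert set(np.unique(samples[0].pixels[:2, :2])) == {0.0, 0.25, 0.5, 1.0}

    def test_constant_slice_maps_to_zeros(self):
        vol = np.ones(TARGET_SHAPE, dtype=np.float32)
        samples = split_and_scale(_vol(vol), 0)
        assert all(float(s.pixels.max()) == 0.0 for s in samples)

    def test_scaling_idempotent(self):
        rng = np.random.default_rng(7)
        vol = _vol(rng.normal(size=TARGET_SHAPE))
        once = split_and_scale(vol, 0)
        again_input = _vol(np.stack([s.pixels for s in once], axis=2))
        twice = split_and_scale(again_input, 0)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-7)

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="expected shape"):
            split_and_scale(_vol(np.zeros((64, 64, 25))), 0)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_slice_range_invariant(self, seed):
        """Non-constant slices scale to min 0 / max 1 exactly."""
        rng = np.random.default_rng(seed)
        vol = _vol(rng.normal(size=TARGET_SHAPE))
        for s in split_and_scale(vol, 0):
            assert float(s.pixels.min()) == 0.0
            assert float(s.pixels.max()) == 1.0


class TestPreprocessScan:
    def test_always_25_samples(self, t1w_volume, dwi_4d_volume):
        for vol, label in ((t1w_volume, 0), (dwi_4d_volume, 1)):
            samples = preprocess_scan(vol, scan_id="x")
            assert len(samples) == 25
            assert [s.slice_index for s in samples] == list(range(25))
            assert {s.four_d_label for s in samples} == {label}

    def test_deterministic(self, t1w_volume):
        a = preprocess_scan(t1w_volume)
        b = preprocess_scan(t1w_volume)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.pixels, sb.pixels)

    def test_count_conservation(self):
        """N scans yield exactly 25N samples; the three catalogued dataset
        sizes follow from the same per-scan constant."""
        rng = np.random.default_rng(8)
        n_per_scan = []
        for _ in range(5):
            shape = tuple(rng.integers(28, 48, size=3))
            vol = _vol(rng.normal(size=shape), np.diag([3.0, 3.0, 4.0, 1.0]))
            n_per_scan.append(len(preprocess_scan(vol)))
        assert n_per_scan == [25] * 5
        assert 25 * 11065 == 276625
        assert 25 * 2369 == 59225
        assert 25 * 7227 == 180675

    def test_sample_cache_round_trip(self, tmp_path, t1w_volume):
        samples = preprocess_scan(t1w_volume, scan_id="scan-1", true_class="T1w")
        path = save_samples(samples, tmp_path / "scan-1.npz")
        back = load_samples(path)
        assert len(back) == 25
        assert back[0].true_class == "T1w"
        np.testing.assert_array_equal(back[7].pixels, samples[7].pixels)
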