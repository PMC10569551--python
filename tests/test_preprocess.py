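"""Pre-processing chain: cropping, padding, smoothing, normalisation, tiling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from murivess import preprocess as pre


class TestExtractRoi:
    def test_bounding_box_of_cubic_mask(self, rng):
        vol = rng.integers(0, 1000, (10, 10, 10)).astype(np.uint16)
        mask = np.zeros_like(vol)
        mask[2:5, 2:5, 2:5] = 1
        roi, geom = pre.extract_roi(vol, mask)
        assert roi.shape == (3, 3, 3)
        assert geom.bbox_low == (2, 2, 2)
        assert geom.bbox_high == (5, 5, 5)
        assert np.array_equal(roi, vol[2:5, 2:5, 2:5])

    def test_full_mask_is_identity(self, rng):
        vol = rng.integers(0, 1000, (6, 7, 8)).astype(np.uint16)
        roi, geom = pre.extract_roi(vol, np.ones_like(vol))
        assert np.array_equal(roi, vol)
        assert geom.bbox_low == (0, 0, 0)

    def test_out_of_mask_voxels_zeroed(self):
        vol = np.full((5, 5, 5), 7, dtype=np.uint16)
        mask = np.zeros_like(vol)
        mask[1, 1, 1] = 1
        mask[3, 3, 3] = 1
        roi, _ = pre.extract_roi(vol, mask)
        assert roi[0, 0, 0] == 7 and roi[2, 2, 2] == 7
        assert roi[0, 0, 2] == 0  # inside bbox, outside mask

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty brain mask"):
            pre.extract_roi(np.ones((4, 4, 4)), np.zeros((4, 4, 4)))


class TestPadToBlock:
    @pytest.mark.parametrize("length,block,expected", [(400, 32, 416), (320, 32, 320), (33, 32, 64)])
    def test_padded_lengths(self, length, block, expected):
        vol = np.ones((length, block, block), dtype=np.uint16)
        geom = pre.RoiGeometry((length, block, block), (0, 0, 0), (length, block, block))
        padded, g2 = pre.pad_to_block(vol, geom, block)
        assert padded.shape[0] == expected
        assert g2.pad[0] == expected - length

    def test_idempotent_and_zero_padded(self, rng):
        vol = rng.integers(1, 9, (10, 10, 10)).astype(np.uint16)
        geom = pre.RoiGeometry((10, 10, 10), (0, 0, 0), (10, 10, 10))
        p1, g1 = pre.pad_to_block(vol, geom, 8)
        p2, g2 = pre.pad_to_block(p1, g1, 8)
        assert np.array_equal(p1, p2) and g1.pad == g2.pad
        assert p1[10:].sum() == 0


class TestGaussianSmooth:
    def test_constant_volume_unchanged(self):
        vol = np.full((9, 9, 9), 5.0, dtype=np.float32)
        out = pre.gaussian_smooth(vol, 1.2)
        assert np.allclose(out, 5.0, atol=1e-5)

    def test_sigma_zero_is_identity(self, rng):
        vol = rng.random((6, 6, 6)).astype(np.float32)
        assert np.array_equal(pre.gaussian_smooth(vol, 0.0), vol)

    def test_interior_impulse_mass_conserved(self):
        # discretized Gaussian kernel normalizes to 1; oracle for sigma=0.5
        vol = np.zeros((21, 21, 21), dtype=np.float32)
        vol[10, 10, 10] = 1.0
        out = pre.gaussian_smooth(vol, 0.5)
        assert abs(float(out.sum()) - 1.0) < 1e-3

    def test_negative_sigma_raises(self):
        with pytest.raises(ValueError):
            pre.gaussian_smooth(np.zeros((4, 4, 4)), -0.1)


class TestMinmaxNormalize:
    def test_observed_intensity_range_maps_to_unit_interval(self):
        # realistic per-stack extremes (min 38, max 24063)
        vol = np.array([[[38, 12000, 24063]]], dtype=np.uint16)
        out = pre.minmax_normalize(vol)
        assert out[0, 0, 0] == 0.0 and out[0, 0, 2] == 1.0

    def test_constant_maps_to_zero(self):
        assert np.all(pre.minmax_normalize(np.full((3, 3, 3), 9)) == 0)

    def test_simple_values(self):
        out = pre.minmax_normalize(np.array([[[0, 5, 10]]], dtype=float))
        assert np.allclose(out, [[[0.0, 0.5, 1.0]]])

    def test_invariant_under_positive_affine_maps(self, rng):
        vol = rng.random((5, 5, 5))
        assert np.allclose(pre.minmax_normalize(vol), pre.minmax_normalize(3.7 * vol + 11.0), atol=1e-6)


class TestPatchify:
    def test_grid_shape_and_count(self, rng):
        vol = rng.random((64, 64, 32)).astype(np.float32)
        geom = pre.RoiGeometry((64, 64, 32), (0, 0, 0), (64, 64, 32))
        ps = pre.patchify(vol, geom, 32)
        assert ps.grid_shape == (2, 2, 1) and len(ps) == 4

    def test_single_patch_equals_input(self, rng):
        vol = rng.random((32, 32, 32)).astype(np.float32)
        geom = pre.RoiGeometry((32, 32, 32), (0, 0, 0), (32, 32, 32))
        ps = pre.patchify(vol, geom, 32)
        assert len(ps) == 1 and np.array_equal(ps.patches[0], vol)

    def test_nondivisible_raises(self):
        geom = pre.RoiGeometry((33, 33, 33), (0, 0, 0), (33, 33, 33))
        with pytest.raises(ValueError):
            pre.patchify(np.zeros((33, 33, 33)), geom, 32)

    def test_lexicographic_ordering(self):
        vol = np.zeros((4, 4, 4), dtype=np.float32)
        # encode grid coordinate into each 2^3 tile
        for iz in range(2):
            for iy in range(2):
                for ix in range(2):
                    vol[iz * 2 : iz * 2 + 2, iy * 2 : iy * 2 + 2, ix * 2 : ix * 2 + 2] = iz * 4 + iy * 2 + ix
        geom = pre.RoiGeometry((4, 4, 4), (0, 0, 0), (4, 4, 4))
        ps = pre.patchify(vol, geom, 2)
        assert [int(p[0, 0, 0]) for p in ps.patches] == list(range(8))


class TestReassemble:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_round_trip_identity_random_geometry(self, seed):
        r = np.random.default_rng(seed)
        shape = tuple(int(x) for x in r.integers(20, 40, 3))
        vol = r.integers(0, 65535, shape).astype(np.uint16)
        mask = np.zeros(shape, dtype=np.uint8)
        lo = [int(r.integers(0, s - 5)) for s in shape]
        hi = [int(r.integers(l + 3, s)) for l, s in zip(lo, shape)]
        mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = 1
        roi, geom = pre.extract_roi(vol, mask)
        roi, geom = pre.pad_to_block(roi, geom, 8)
        out = pre.reassemble(pre.patchify(roi, geom, 8))
        expected = np.where(mask != 0, vol, 0)
        assert np.array_equal(out, expected)

    def test_missing_patch_raises(self, rng):
        vol = rng.random((16, 16, 16)).astype(np.float32)
        geom = pre.RoiGeometry((16, 16, 16), (0, 0, 0), (16, 16, 16))
        ps = pre.patchify(vol, geom, 8)
        ps.patches.pop()
        with pytest.raises(ValueError):
            pre.reassemble(ps)


def test_geometry_json_round_trip():
    geom = pre.RoiGeometry((100, 90, 80), (3, 4, 5), (60, 70, 80), (2, 0, 1))
    assert pre.RoiGeometry.from_json(geom.to_json()) == geom
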