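"""Volume I/O, pre-processing and virtual slicing."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st

from perikymata import volume_io as vio


class TestReadWrite:
    def test_zero_stack_roundtrip_shape(self, tmp_path):
        d = tmp_path / "stack"
        d.mkdir()
        for i in range(3):
            tifffile.imwrite(d / f"s{i:03d}.tif",
                             np.zeros((4, 4), dtype=np.uint16))
        vol = vio.read_tiff_stack(d, 4.96)
        assert vol.shape == (3, 4, 4)
        assert not vol.voxels.any()
        assert vol.bit_depth == 16

    def test_multipage_roundtrip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = vio.Volume(rng.random((5, 6, 7)).astype(np.float32), 2.5)
        path = vio.write_tiff_stack(vol, tmp_path / "v.tif")
        back = vio.read_tiff_stack(path, 2.5)
        np.testing.assert_array_equal(back.voxels, vol.voxels)

    def test_lexicographic_slice_order(self, tmp_path):
        d = tmp_path / "stack"
        d.mkdir()
        # written out of order; lexicographic sort restores s002 first
        tifffile.imwrite(d / "s010.tif",
                         np.full((2, 2), 10, dtype=np.uint16))
        tifffile.imwrite(d / "s002.tif",
                         np.full((2, 2), 2, dtype=np.uint16))
        vol = vio.read_tiff_stack(d, 1.0)
        assert sorted(["s002.tif", "s010.tif"]) == ["s002.tif", "s010.tif"]
        assert vol.voxels[0, 0, 0] == 2 and vol.voxels[1, 0, 0] == 10

    def test_mixed_shapes_rejected(self, tmp_path):
        d = tmp_path / "stack"
        d.mkdir()
        tifffile.imwrite(d / "a.tif", np.zeros((4, 4), dtype=np.uint16))
        tifffile.imwrite(d / "b.tif", np.zeros((4, 5), dtype=np.uint16))
        with pytest.raises(vio.FormatError):
            vio.read_tiff_stack(d, 1.0)

    def test_empty_directory_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            vio.read_tiff_stack(tmp_path, 1.0)


class TestTo16Bit:
    def test_endpoints_and_midpoint(self):
        vol = vio.Volume(np.array([[[0.0, 5.0, 10.0, -3.0, 42.0]]]), 1.0)
        out = vio.to_16bit(vol, 0.0, 10.0)
        assert list(out.voxels.ravel()) == [0, 32768, 65535, 0, 65535]
        assert out.bit_depth == 16

    def test_full_range_after_min_max_window(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(4, 5, 6))
        out = vio.to_16bit(vio.Volume(v, 1.0), v.min(), v.max())
        assert out.voxels.min() == 0 and out.voxels.max() == 65535
        # brute-force per-voxel check of the linear map
        expect = np.floor((v - v.min()) / (v.max() - v.min())
                          * 65535.0 + 0.5).astype(np.uint16)
        np.testing.assert_array_equal(out.voxels, expect)

    def test_invalid_window(self):
        vol = vio.Volume(np.zeros((1, 2, 2)), 1.0)
        with pytest.raises(ValueError):
            vio.to_16bit(vol, 5.0, 5.0)

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=32))
    def test_monotone(self, values):
        v = np.asarray(values).reshape(1, 1, -1)
        out = vio.to_16bit(vio.Volume(v, 1.0), -1e6, 1e6).voxels.ravel()
        order = np.argsort(v.ravel(), kind="stable")
        assert np.all(np.diff(out[order].astype(int)) >= 0)


class TestConcat:
    def test_dimension_addition(self):
        a = vio.Volume(np.zeros((5, 4, 4)), 1.0)
        b = vio.Volume(np.ones((5, 4, 4)), 1.0)
        out = vio.concat_subscans([a, b])
        assert out.shape == (10, 4, 4)

    def test_single_part_identity(self):
        a = vio.Volume(np.arange(24.0).reshape(2, 3, 4), 1.0)
        np.testing.assert_array_equal(vio.concat_subscans([a]).voxels,
                                      a.voxels)

    def test_global_z_maps_to_correct_part(self):
        parts = [vio.Volume(np.full((n, 2, 2), i, dtype=float), 1.0)
                 for i, n in enumerate([2, 3, 4])]
        out = vio.concat_subscans(parts)
        # index bookkeeping oracle
        starts = np.cumsum([0, 2, 3])
        for i, s in enumerate(starts):
            assert out.voxels[s, 0, 0] == i

    def test_shape_mismatch_rejected(self):
        a = vio.Volume(np.zeros((2, 4, 4)), 1.0)
        b = vio.Volume(np.zeros((2, 4, 5)), 1.0)
        with pytest.raises(vio.FormatError):
            vio.concat_subscans([a, b])


class TestBin2:
    def test_constant_preserved(self):
        out = vio.bin2(vio.Volume(np.full((4, 4, 4), 7.5), 1.0))
        assert np.allclose(out.voxels, 7.5)

    def test_voxel_size_doubles(self):
        out = vio.bin2(vio.Volume(np.zeros((4, 4, 4)), 4.96))
        assert out.voxel_size_um == pytest.approx(9.92)

    def test_block_means_match_brute_force(self):
        rng = np.random.default_rng(2)
        v = rng.random((4, 4, 4))
        out = vio.bin2(vio.Volume(v, 1.0)).voxels
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    block = v[2*i:2*i+2, 2*j:2*j+2, 2*k:2*k+2]
                    assert out[i, j, k] == pytest.approx(block.mean())

    def test_odd_trailing_planes_dropped_and_mean_conserved(self):
        rng = np.random.default_rng(3)
        v = rng.random((6, 6, 6))
        out = vio.bin2(vio.Volume(v, 1.0))
        assert out.shape == (3, 3, 3)
        assert out.voxels.mean() == pytest.approx(v.mean(), rel=1e-6)
        odd = vio.bin2(vio.Volume(rng.random((5, 7, 4)), 1.0))
        assert odd.shape == (2, 3, 2)


class TestSuppressRings:
    def _ring_slice(self):
        yy, xx = np.mgrid[0:101, 0:101]
        r = np.hypot(yy - 50, xx - 50)
        base = 10 + 0.02 * yy
        ring = np.exp(-0.5 * ((r - 20) / 1.5) ** 2)
        return base, ring, r

    def test_ring_residual_below_fifth_of_amplitude(self):
        base, ring, r = self._ring_slice()
        vol = vio.Volume((base + ring)[None], 1.0)
        out = vio.suppress_rings(vol, 21)
        resid = out.voxels[0] - base
        band = (r > 15) & (r < 25)
        assert np.abs(resid[band]).mean() < 0.2

    def test_mean_preserved_and_flat_unchanged(self):
        base, ring, _ = self._ring_slice()
        vol = vio.Volume((base + ring)[None], 1.0)
        out = vio.suppress_rings(vol, 21)
        assert out.voxels.mean() == pytest.approx(vol.voxels.mean(),
                                                  rel=5e-3)
        flat = vio.Volume(np.full((2, 64, 64), 5.0), 1.0)
        np.testing.assert_allclose(vio.suppress_rings(flat, 21).voxels, 5.0)

    def test_ringless_slice_near_identity(self):
        yy, xx = np.mgrid[0:64, 0:64]
        sl = (10 + 0.05 * yy + 0.03 * xx)[None]
        out = vio.suppress_rings(vio.Volume(sl, 1.0), 21)
        rms = np.sqrt(((out.voxels - sl) ** 2).mean())
        assert rms / sl.mean() < 0.01

    def test_bad_kernel_rejected(self):
        vol = vio.Volume(np.zeros((1, 8, 8)), 1.0)
        with pytest.raises(ValueError):
            vio.suppress_rings(vol, 4)
        with pytest.raises(ValueError):
            vio.suppress_rings(vol, 99)


class TestReslice:
    def test_identity_plane_bit_exact(self):
        rng = np.random.default_rng(4)
        vol = vio.Volume(rng.random((8, 9, 10)), 3.0)
        plane = vio.SlicePlane(origin_um=(4 * 3.0, 0, 0), normal=(1, 0, 0),
                               thickness_um=3.0)
        np.testing.assert_array_equal(vio.reslice(vol, plane),
                                      vol.voxels[4])

    def test_two_plane_mean_on_linear_gradient(self):
        g = np.arange(8.0)[:, None, None] * np.ones((1, 9, 10))
        vol = vio.Volume(g, 1.0)
        plane = vio.SlicePlane(origin_um=(3.5, 0, 0), normal=(1, 0, 0),
                               thickness_um=2.0)
        np.testing.assert_allclose(vio.reslice(vol, plane), 3.5)

    def test_100um_slab_averages_21_planes(self):
        # impulse volume: the number of averaged planes follows from the
        # response amplitude, ceil(100 / 4.96) = 21
        v = np.zeros((41, 3, 3))
        v[20] = 1.0
        vol = vio.Volume(v, 4.96)
        plane = vio.SlicePlane(origin_um=(20 * 4.96, 0, 0),
                               normal=(1, 0, 0), thickness_um=100.0)
        out = vio.reslice(vol, plane)
        assert out[1, 1] == pytest.approx(1.0 / 21)

    def test_oblique_slab_runs(self):
        g = np.arange(8.0)[:, None, None] * np.ones((1, 9, 10))
        vol = vio.Volume(g, 1.0)
        n = np.array([0, 1.0, 1.0]) / np.sqrt(2)
        plane = vio.SlicePlane(origin_um=(4, 4, 5), normal=n,
                               thickness_um=1.0)
        out = vio.reslice(vol, plane)
        assert out.ndim == 2 and out.size > 0

    def test_plane_outside_volume_rejected(self):
        vol = vio.Volume(np.zeros((4, 4, 4)), 1.0)
        plane = vio.SlicePlane(origin_um=(100, 0, 0), normal=(1, 0, 0),
                               thickness_um=1.0)
        with pytest.raises(vio.GeometryError):
            vio.reslice(vol, plane)
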