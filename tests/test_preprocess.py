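"""Brightness calibration, SNR enhancement and block partitioning."""

import numpy as np
import pytest

from plaqseg3d.preprocess import (NoTissueError, calibrate_brightness,
                                  compute_tissue_mask, enhance_snr,
                                  extract_block, partition_blocks)
from plaqseg3d.synthgen import SceneConfig, generate_scene
from plaqseg3d.volio import SegmentationMask, VolumeStack


def _vol(data, spacing=(1, 1, 1)):
    return VolumeStack(np.asarray(data, np.float32), spacing)


class TestTissueMask:
    def test_bright_ellipsoid_recovered(self):
        z, y, x = np.ogrid[:32, :32, :32]
        ell = ((z - 16) / 12.0) ** 2 + ((y - 16) / 13.0) ** 2 \
            + ((x - 16) / 13.0) ** 2 <= 1
        vol = _vol(np.where(ell, 0.6, 0.0))
        mask = compute_tissue_mask(vol)
        recall = (mask.data & ell).sum() / ell.sum()
        assert recall > 0.95

    def test_constant_volume_is_error(self):
        with pytest.raises(NoTissueError):
            compute_tissue_mask(_vol(np.full((16, 16, 16), 0.5)))

    def test_synthetic_scene_recall(self):
        scene = generate_scene(SceneConfig(shape=(48, 64, 64), n_plaques=5,
                                           noise_sd=0.01, seed=11))
        mask = compute_tissue_mask(scene.volume)
        brain = scene.brain_mask.data
        assert (mask.data & brain).sum() / brain.sum() >= 0.95


class TestCalibration:
    def test_constant_profile_is_identity(self):
        data = np.random.default_rng(0).random((10, 8, 8)).astype(np.float32)
        data = np.broadcast_to(data[0], (10, 8, 8)).copy()
        tissue = SegmentationMask(np.ones_like(data, bool))
        out, prof = calibrate_brightness(_vol(data), tissue)
        np.testing.assert_allclose(out.data, data, rtol=1e-6)
        np.testing.assert_allclose(prof.gain, 1.0, rtol=1e-6)

    def test_double_brightness_slice_halved(self):
        data = np.full((5, 6, 6), 0.2, np.float32)
        data[1] = 0.4  # m(1) = 2 * m(z_mid)
        tissue = SegmentationMask(np.ones_like(data, bool))
        out, prof = calibrate_brightness(_vol(data), tissue)
        np.testing.assert_allclose(out.data[1], 0.2, rtol=1e-6)
        assert prof.gain[1] == pytest.approx(0.5)
        assert prof.gain[prof.mid_index[0]] == pytest.approx(1.0)

    def test_removes_synthetic_depth_decay(self):
        profile = 1.0 - 0.4 * np.arange(48) / 47
        scene = generate_scene(SceneConfig(shape=(48, 64, 64), n_plaques=0,
                                           noise_sd=0.0, depth_decay=profile,
                                           background_level=0.3, seed=4))
        tissue = scene.brain_mask
        out, _ = calibrate_brightness(scene.volume, tissue)
        means = np.array([out.data[k][tissue.data[k]].mean()
                          for k in range(48) if tissue.data[k].any()])
        assert means.std() / means.mean() < 0.01

    def test_idempotent(self):
        scene = generate_scene(SceneConfig(shape=(32, 48, 48), n_plaques=3,
                                           size_class_mix=(0.6, 0.4, 0.0),
                                           noise_sd=0.0,
                                           depth_decay=1 - 0.3 * np.arange(32) / 31,
                                           seed=6))
        tissue = scene.brain_mask
        once, _ = calibrate_brightness(scene.volume, tissue)
        twice, _ = calibrate_brightness(once, tissue)
        assert np.abs(twice.data - once.data).max() < 1e-6

    def test_linear_in_global_scale(self):
        scene = generate_scene(SceneConfig(shape=(24, 32, 32), n_plaques=2,
                                           size_class_mix=(1.0, 0.0, 0.0),
                                           noise_sd=0.0, seed=8))
        tissue = scene.brain_mask
        base, _ = calibrate_brightness(scene.volume, tissue)
        scaled_in = VolumeStack(0.5 * scene.volume.data, scene.volume.spacing)
        scaled, _ = calibrate_brightness(scaled_in, tissue)
        np.testing.assert_allclose(scaled.data, 0.5 * base.data,
                                   rtol=1e-5, atol=1e-7)

    def test_empty_slice_keeps_gain_one(self):
        data = np.full((4, 4, 4), 0.5, np.float32)
        tis = np.ones((4, 4, 4), bool)
        tis[0] = False
        with pytest.warns(UserWarning):
            _, prof = calibrate_brightness(_vol(data), SegmentationMask(tis))
        assert prof.gain[0] == 1.0


class TestSNR:
    def test_constant_volume_is_fixed_point(self):
        v = _vol(np.full((16, 16, 16), 0.37))
        out = enhance_snr(v, 2.0)
        np.testing.assert_allclose(out.data, 0.37, atol=1e-6)

    def test_impulse_response_peak_matches_gaussian_normaliser(self):
        data = np.zeros((33, 33, 33), np.float32)
        data[16, 16, 16] = 1.0
        out = enhance_snr(_vol(data), 2.0)
        expected = (2 * np.pi * 4.0) ** -1.5  # 3D Gaussian at the origin
        assert out.data[16, 16, 16] == pytest.approx(expected, abs=1e-4)

    def test_mass_conserved_for_interior_blob(self):
        data = np.zeros((32, 32, 32), np.float32)
        data[12:20, 12:20, 12:20] = 0.5
        out = enhance_snr(_vol(data), 2.0)
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            enhance_snr(_vol(np.zeros((4, 4, 4))), 0.0)


class TestPartition:
    def test_single_full_tissue_block(self):
        v = _vol(np.ones((75, 256, 256)))
        t = SegmentationMask(np.ones((75, 256, 256), bool))
        grid = partition_blocks(v, t)
        assert grid.n_blocks == 1 and grid.kept.all()

    def test_block_count_from_ceil_division(self):
        v = _vol(np.ones((75, 512, 512)))
        t = SegmentationMask(np.ones((75, 512, 512), bool))
        grid = partition_blocks(v, t)
        assert grid.n_blocks == 4

    def test_one_percent_boundary_exact(self):
        # 256*256*75 = 4,915,200 voxels: 49,151 tissue voxels (0.99998%)
        # is excluded, 49,152 (exactly 1%) is kept
        v = _vol(np.zeros((75, 256, 256)))
        for n_tissue, expect_kept in [(49151, False), (49152, True)]:
            t = np.zeros((75, 256, 256), bool)
            t.ravel()[:n_tissue] = True
            grid = partition_blocks(v, SegmentationMask(t))
            assert bool(grid.kept[0]) is expect_kept

    def test_padding_and_reassembly_lossless(self, rng):
        data = rng.random((30, 50, 70)).astype(np.float32)
        tissue = SegmentationMask(np.ones_like(data, bool))
        grid = partition_blocks(_vol(data), tissue, block_shape=(16, 32, 32),
                                min_tissue_frac=0.0)
        padded = np.zeros(grid.padded_shape, np.float32)
        for i in range(grid.n_blocks):
            o = grid.origins[i]
            bs = grid.block_shape
            padded[o[0]:o[0]+bs[0], o[1]:o[1]+bs[1], o[2]:o[2]+bs[2]] = \
                extract_block(data, grid, i)
        np.testing.assert_array_equal(padded[:30, :50, :70], data)

    def test_every_tissue_voxel_in_exactly_one_block(self):
        data = np.ones((20, 20, 20), np.float32)
        t = SegmentationMask(np.ones_like(data, bool))
        grid = partition_blocks(_vol(data), t, block_shape=(8, 8, 8))
        counts = sum(int(t.data[o[0]:o[0]+8, o[1]:o[1]+8, o[2]:o[2]+8].sum())
                     for o in grid.origins)
        assert counts == t.data.sum()
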