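"""Joint histogram, 2D-Otsu threshold search vs brute force, and montage."""

from fractions import Fraction

import numpy as np
import pytest

from plaqseg3d.preprocess import partition_blocks
from plaqseg3d.segment2dotsu import (DegenerateHistogramError, JointHistogram,
                                     joint_histogram, montage, otsu1d,
                                     otsu2d_threshold, segment_block)
from plaqseg3d.volio import SegmentationMask, VolumeStack


class TestJointHistogram:
    def test_constant_inputs_single_cell(self):
        block = np.full((4, 4, 4), 0.5)
        prm = np.full((4, 4, 4), 0.25)
        roi = np.ones((4, 4, 4), bool)
        roi[0] = False
        h = joint_histogram(block, prm, (64, 64), roi)
        assert h.total == 48
        assert (h.counts > 0).sum() == 1

    def test_two_diagonal_clusters(self):
        block = np.concatenate([np.full((2, 4, 4), 0.2), np.full((2, 4, 4), 0.8)])
        prm = np.concatenate([np.zeros((2, 4, 4)), np.ones((2, 4, 4))])
        h = joint_histogram(block, prm, (64, 64))
        nz = np.argwhere(h.counts > 0)
        assert len(nz) == 2
        assert h.counts[tuple(nz[0])] == h.counts[tuple(nz[1])] == 32

    def test_total_equals_roi_size(self, rng):
        block, prm = rng.random((6, 6, 6)), rng.random((6, 6, 6))
        roi = rng.random((6, 6, 6)) < 0.5
        assert joint_histogram(block, prm, (16, 16), roi).total == roi.sum()

    def test_empty_roi_is_error(self):
        with pytest.raises(ValueError, match="empty ROI"):
            joint_histogram(np.zeros((2, 2, 2)), np.zeros((2, 2, 2)),
                            roi=np.zeros((2, 2, 2), bool))


def brute_force_otsu2d(counts):
    """Exact-rational exhaustive search mirroring the documented criterion."""
    bi, bp = counts.shape
    n_total = int(counts.sum())
    best = None
    for ti in range(bi):
        for tp in range(bp):
            bg = counts[:ti + 1, :tp + 1]
            fg = counts[ti + 1:, tp + 1:]
            n0, n1 = int(bg.sum()), int(fg.sum())
            if n0 == 0 or n1 == 0:
                continue
            i_idx = np.arange(bi)
            p_idx = np.arange(bp)
            si0 = int((bg.sum(axis=1) * i_idx[:ti + 1]).sum())
            sp0 = int((bg.sum(axis=0) * p_idx[:tp + 1]).sum())
            si1 = int((fg.sum(axis=1) * i_idx[ti + 1:]).sum())
            sp1 = int((fg.sum(axis=0) * p_idx[tp + 1:]).sum())
            di = Fraction(si1, n1) - Fraction(si0, n0)
            dp = Fraction(sp1, n1) - Fraction(sp0, n0)
            obj = Fraction(n0 * n1, n_total ** 2) * (di * di + dp * dp)
            if best is None or obj > best[0]:
                best = (obj, ti, tp)
    return best


class TestOtsu2D:
    def test_two_diagonal_clusters_tie_break(self):
        counts = np.zeros((64, 64), np.int64)
        counts[10, 10] = 40
        counts[50, 50] = 25
        thr = otsu2d_threshold(JointHistogram(counts, None, None))
        assert (thr.t_intensity, thr.t_prm) == (10, 10)
        fg = counts[thr.t_intensity + 1:, thr.t_prm + 1:].sum()
        assert fg == 25

    @pytest.mark.parametrize("seed", range(12))
    def test_equals_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        counts = np.zeros((16, 16), np.int64)
        cells = rng.integers(0, 16, size=(30, 2))
        for c in cells:
            counts[tuple(c)] += int(rng.integers(1, 50))
        try:
            thr = otsu2d_threshold(JointHistogram(counts, None, None))
        except DegenerateHistogramError:
            assert brute_force_otsu2d(counts) is None
            return
        obj, ti, tp = brute_force_otsu2d(counts)
        assert (thr.t_intensity, thr.t_prm) == (ti, tp)
        assert thr.objective_value == pytest.approx(float(obj), rel=1e-9)

    def test_degenerate_prm_axis_reduces_to_1d_otsu(self, rng):
        marginal = rng.integers(0, 40, size=64)
        marginal[[5, 40]] += 100  # clear bimodal structure
        counts = np.zeros((64, 64), np.int64)
        counts[:, 7] = marginal
        thr = otsu2d_threshold(JointHistogram(counts, None, None))
        t1d, _ = otsu1d(marginal)
        assert thr.t_intensity == t1d
        assert thr.t_prm == 6  # all PRM mass strictly above the threshold

    def test_degenerate_intensity_axis_symmetric(self, rng):
        marginal = np.zeros(64, np.int64)
        marginal[3] = 50
        marginal[60] = 50
        counts = np.zeros((64, 64), np.int64)
        counts[9, :] = marginal
        thr = otsu2d_threshold(JointHistogram(counts, None, None))
        assert thr.t_prm == otsu1d(marginal)[0]
        assert thr.t_intensity == 8

    def test_single_cell_is_error(self):
        counts = np.zeros((8, 8), np.int64)
        counts[3, 3] = 10
        with pytest.raises(DegenerateHistogramError):
            otsu2d_threshold(JointHistogram(counts, None, None))

    def test_histogram_order_invariance(self, rng):
        block = rng.random((8, 8, 8))
        prm = rng.random((8, 8, 8))
        h1 = joint_histogram(block, prm, (32, 32))
        perm = rng.permutation(block.size)
        h2 = joint_histogram(block.ravel()[perm].reshape(block.shape),
                             prm.ravel()[perm].reshape(prm.shape), (32, 32))
        t1, t2 = otsu2d_threshold(h1), otsu2d_threshold(h2)
        assert (t1.t_intensity, t1.t_prm) == (t2.t_intensity, t2.t_prm)

    def test_increasing_separation_never_lowers_objective(self):
        # moving the foreground cluster further from the background cluster
        # (masses fixed) cannot decrease the between-class criterion
        prev = -1.0
        for hi in range(20, 60, 8):
            counts = np.zeros((64, 64), np.int64)
            counts[5, 5] = 30
            counts[hi, hi] = 20
            obj = otsu2d_threshold(JointHistogram(counts, None, None)).objective_value
            assert obj >= prev
            prev = obj

    def test_1d_otsu_matches_scikit_image(self, rng):
        from skimage.filters import threshold_otsu

        samples = np.concatenate([rng.normal(0.3, 0.03, 400),
                                  rng.normal(0.7, 0.03, 300)])
        samples = np.clip(samples, 0, 0.999)
        counts = np.histogram(samples, bins=64, range=(0, 1))[0]
        t, _ = otsu1d(counts)
        # skimage returns an intensity value; ours is the last background bin
        t_sk = threshold_otsu(samples, nbins=64)
        assert abs((t + 0.5) / 64 - t_sk) < 2 / 64


class TestSegmentBlock:
    def test_zero_prm_falls_back_to_empty_mask(self):
        with pytest.warns(UserWarning):
            out = segment_block(np.random.default_rng(0).random((8, 8, 8)),
                                np.zeros((8, 8, 8)))
        assert out.voxel_count == 0

    def test_mask_contained_in_roi(self, rng):
        block = rng.random((12, 12, 12))
        prm = rng.random((12, 12, 12))
        roi = rng.random((12, 12, 12)) < 0.4
        out = segment_block(block, prm, roi)
        assert not (out.data & ~roi).any()

    def test_bright_blob_with_prm_support_recovered(self):
        z, y, x = np.ogrid[:16, :16, :16]
        blob = ((z - 8) ** 2 + (y - 8) ** 2 + (x - 8) ** 2) <= 16
        block = np.where(blob, 0.9, 0.1) + np.random.default_rng(1).normal(
            0, 0.01, (16, 16, 16))
        prm = np.where(blob, 0.8, 0.01)
        out = segment_block(np.clip(block, 0, 1), prm)
        inter = (out.data & blob).sum()
        dice = 2 * inter / (out.data.sum() + blob.sum())
        assert dice >= 0.9


class TestMontage:
    def _grid(self, shape, block_shape):
        v = VolumeStack(np.zeros(shape, np.float32))
        t = SegmentationMask(np.ones(shape, bool))
        return partition_blocks(v, t, block_shape, 0.0)

    def test_single_block_identity(self, rng):
        grid = self._grid((8, 8, 8), (8, 8, 8))
        m = rng.random((8, 8, 8)) < 0.3
        out = montage(grid, {0: m})
        np.testing.assert_array_equal(out.data, m)

    def test_straddling_plaque_one_component(self):
        from plaqseg3d.quantify import label_components

        grid = self._grid((8, 16, 8), (8, 8, 8))
        left = np.zeros((8, 8, 8), bool)
        right = np.zeros((8, 8, 8), bool)
        left[3:6, 5:8, 3:6] = True    # touches the y-boundary
        right[3:6, 0:3, 3:6] = True   # continues across it
        out = montage(grid, {0: left, 1: right})
        assert len(label_components(out)) == 1
        assert out.voxel_count == left.sum() + right.sum()

    def test_all_empty_blocks_give_empty_mask(self):
        grid = self._grid((8, 16, 16), (8, 8, 8))
        masks = {i: np.zeros((8, 8, 8), bool) for i in range(grid.n_blocks)}
        assert montage(grid, masks).voxel_count == 0

    def test_padding_cropped_to_volume_shape(self, rng):
        grid = self._grid((6, 10, 10), (8, 8, 8))
        masks = {i: np.ones((8, 8, 8), bool) for i in range(grid.n_blocks)}
        out = montage(grid, masks)
        assert out.shape == (6, 10, 10)
        assert out.data.all()

    def test_missing_kept_block_is_error(self):
        grid = self._grid((8, 16, 8), (8, 8, 8))
        with pytest.raises(ValueError, match="missing mask"):
            montage(grid, {0: np.zeros((8, 8, 8), bool)})

    def test_shape_mismatch_names_block(self):
        grid = self._grid((8, 8, 8), (8, 8, 8))
        with pytest.raises(ValueError, match="block 0"):
            montage(grid, {0: np.zeros((4, 4, 4), bool)})

    def test_voxel_count_conserved(self, rng):
        grid = self._grid((16, 16, 16), (8, 8, 8))
        masks = {i: rng.random((8, 8, 8)) < 0.2 for i in range(grid.n_blocks)}
        out = montage(grid, masks)
        assert out.voxel_count == sum(int(m.sum()) for m in masks.values())
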