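"""Anchors, target assignment, box coding, NMS and short training runs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plaqseg3d.detect3d import (AnchorRangeWarning, AnchorSet, DetectorModel,
                                TrainConfig, anchor_array, assign_targets,
                                decode_boxes, detect, encode_boxes,
                                generate_anchors, load_checkpoint, nms3d,
                                save_checkpoint, train)
from plaqseg3d.hrnet3d import HRNetConfig
from plaqseg3d.synthgen import SceneConfig, generate_scene
from plaqseg3d.volio import BoundingBox3D, boxes_to_array

TINY_BACKBONE = HRNetConfig(n_branches=2, base_channels=4, n_stages=1)


class TestAnchors:
    def test_single_position_single_size(self):
        boxes = generate_anchors((1, 1, 1), AnchorSet(sizes=(6,), stride=4))
        assert len(boxes) == 1
        b = boxes[0]
        assert b.size == (6, 6, 6)
        assert b.center == (2.0, 2.0, 2.0)

    def test_count_is_positions_times_sizes(self):
        arr = anchor_array((16, 16, 8), AnchorSet(sizes=(6, 12, 24)))
        assert arr.shape == (16 * 16 * 8 * 3, 6)

    def test_all_edges_within_range(self):
        arr = anchor_array((4, 4, 4), AnchorSet())
        edges = arr[:, 3:] - arr[:, :3]
        assert edges.min() >= 6 and edges.max() <= 28

    def test_ordering_position_major_size_minor(self):
        a = anchor_array((1, 1, 2), AnchorSet(sizes=(6, 10)))
        # first two rows share the first lattice position
        c0 = (a[0, :3] + a[0, 3:]) / 2
        c1 = (a[1, :3] + a[1, 3:]) / 2
        np.testing.assert_array_equal(c0, c1)
        assert (a[0, 3:] - a[0, :3])[0] == 6
        assert (a[1, 3:] - a[1, :3])[0] == 10

    def test_out_of_range_size_rejected(self):
        with pytest.raises(ValueError):
            AnchorSet(sizes=(4,))


class TestBoxCoding:
    @settings(deadline=None, max_examples=60)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_encode_decode_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        anchors = anchor_array((2, 2, 2), AnchorSet(sizes=(6, 14)))
        sizes = rng.uniform(3, 30, size=(len(anchors), 3))
        centers = rng.uniform(0, 20, size=(len(anchors), 3))
        boxes = np.concatenate([centers - sizes / 2, centers + sizes / 2], axis=1)
        back = decode_boxes(encode_boxes(boxes, anchors), anchors)
        np.testing.assert_allclose(back, boxes, atol=1e-6)


class TestAssignment:
    def test_no_gt_all_negative(self):
        anchors = anchor_array((2, 2, 2), AnchorSet(sizes=(6,)))
        labels, _, _ = assign_targets(anchors, np.zeros((0, 6)), TrainConfig())
        assert (labels == 0).all()

    def test_exact_anchor_match_zero_regression(self):
        anchors = anchor_array((2, 2, 2), AnchorSet(sizes=(6,)))
        gt = anchors[3:4].copy()
        labels, matched, targets = assign_targets(anchors, gt, TrainConfig())
        assert labels[3] == 1
        np.testing.assert_allclose(targets[3], 0.0, atol=1e-12)

    def test_low_iou_gt_still_gets_argmax_anchor(self):
        # a gt overlapping every anchor below iou_pos is still claimed by its
        # best anchor (exhaustive scan over a 32^3 lattice)
        anchors = anchor_array((8, 8, 8), AnchorSet(sizes=(6,)))
        gt = np.array([[0.0, 0.0, 0.0, 14.0, 14.0, 14.0]])
        from plaqseg3d.volio import iou_matrix

        iou = iou_matrix(anchors, gt)
        assert iou.max() < 0.5  # between the thresholds
        labels, matched, _ = assign_targets(anchors, gt, TrainConfig())
        assert labels[int(iou.argmax())] == 1
        assert matched[int(iou.argmax())] == 0

    def test_oversized_gt_warns(self):
        anchors = anchor_array((2, 2, 2), AnchorSet(sizes=(6,)))
        gt = np.array([[0.0, 0.0, 0.0, 60.0, 60.0, 60.0]])
        with pytest.warns(AnchorRangeWarning):
            assign_targets(anchors, gt, TrainConfig())


class TestNMS:
    def test_duplicate_boxes_collapse(self):
        boxes = np.array([[0, 0, 0, 4, 4, 4], [0, 0, 0, 4, 4, 4]], float)
        keep = nms3d(boxes, np.array([0.9, 0.8]), 0.3)
        assert keep.tolist() == [0]

    def test_disjoint_boxes_all_kept(self):
        boxes = np.array([[0, 0, 0, 4, 4, 4], [10, 10, 10, 14, 14, 14]], float)
        assert len(nms3d(boxes, np.array([0.5, 0.9]), 0.3)) == 2

    def test_permutation_invariance(self, rng):
        lo = rng.integers(0, 20, size=(30, 3))
        boxes = np.concatenate([lo, lo + rng.integers(4, 10, (30, 3))], 1).astype(float)
        scores = np.round(rng.random(30), 2)  # force some score ties
        kept_a = {tuple(boxes[i]) for i in nms3d(boxes, scores, 0.3)}
        perm = rng.permutation(30)
        kept_b = {tuple(boxes[perm][i]) for i in nms3d(boxes[perm], scores[perm], 0.3)}
        assert kept_a == kept_b

    def test_survivors_respect_iou_bound(self, rng):
        from plaqseg3d.volio import iou_matrix

        lo = rng.integers(0, 15, size=(40, 3))
        boxes = np.concatenate([lo, lo + rng.integers(3, 12, (40, 3))], 1).astype(float)
        scores = rng.random(40)
        keep = nms3d(boxes, scores, 0.3)
        m = iou_matrix(boxes[keep], boxes[keep])
        np.fill_diagonal(m, 0)
        assert m.max() <= 0.3 + 1e-12


def _tiny_dataset(n_blocks=2, shape=(32, 32, 32)):
    blocks, boxes = [], []
    for s in range(n_blocks):
        sc = generate_scene(SceneConfig(shape=shape, n_plaques=3,
                                        size_class_mix=(0.5, 0.5, 0.0),
                                        noise_sd=0.01, seed=50 + s))
        blocks.append(sc.volume.data)
        boxes.append(sc.boxes)
    return blocks, boxes


class TestTraining:
    def test_zero_lr_leaves_parameters_unchanged(self):
        blocks, boxes = _tiny_dataset(1)
        model = DetectorModel(TINY_BACKBONE, seed=0)
        before = {k: v.copy() for k, v in model.named_state().items()
                  if "running" not in k}
        train(model, blocks, boxes, TrainConfig(lr=0.0, max_iterations=3, seed=0))
        after = model.named_state()
        for k, v in before.items():
            np.testing.assert_array_equal(after[k], v)

    def test_same_seed_identical_loss_history(self):
        blocks, boxes = _tiny_dataset(1)
        histories = []
        for _ in range(2):
            model = DetectorModel(TINY_BACKBONE, seed=1)
            h = train(model, blocks, boxes,
                      TrainConfig(max_iterations=4, seed=3))
            histories.append(h["loss"])
        assert histories[0] == histories[1]

    def test_loss_decreases_on_fixture(self):
        blocks, boxes = _tiny_dataset(2)
        model = DetectorModel(TINY_BACKBONE, seed=0)
        h = train(model, blocks, boxes, TrainConfig(max_iterations=40, seed=0))
        assert np.mean(h["loss"][-10:]) < np.mean(h["loss"][:10])

    def test_requires_at_least_one_box(self):
        with pytest.raises(ValueError):
            train(DetectorModel(TINY_BACKBONE), [np.zeros((16, 16, 16))], [[]],
                  TrainConfig(max_iterations=1))


class TestDetectAndCheckpoint:
    def test_zero_block_yields_no_confident_detections(self):
        model = DetectorModel(TINY_BACKBONE, seed=0)
        dets, rpn = detect(model, np.zeros((16, 16, 16), np.float32),
                           score_thresh=0.5)
        assert dets == []
        assert rpn.score_map.shape == (5, 4, 4, 4)

    def test_detections_have_scores_and_valid_boxes(self):
        blocks, boxes = _tiny_dataset(1)
        model = DetectorModel(TINY_BACKBONE, seed=0)
        train(model, blocks, boxes, TrainConfig(max_iterations=25, seed=0))
        dets, _ = detect(model, blocks[0], score_thresh=0.05)
        for d in dets:
            assert d.score is not None and 0 <= d.score <= 1
            assert all(0 <= a < b <= s for a, b, s in
                       zip(d.zyx_min, d.zyx_max, blocks[0].shape))

    def test_checkpoint_round_trip_bit_exact(self, tmp_path):
        blocks, boxes = _tiny_dataset(1)
        model = DetectorModel(TINY_BACKBONE, seed=0)
        train(model, blocks, boxes, TrainConfig(max_iterations=3, seed=0))
        path = save_checkpoint(model, tmp_path / "ckpt.npz")
        clone = load_checkpoint(path)
        for k, v in model.named_state().items():
            np.testing.assert_array_equal(clone.named_state()[k], v)
        a, _ = detect(model, blocks[0], score_thresh=0.1)
        b, _ = detect(clone, blocks[0], score_thresh=0.1)
        assert boxes_to_array(a).tolist() == boxes_to_array(b).tolist()


def test_weak_supervision_interface_excludes_masks():
    """Training consumes blocks and boxes only; masks cannot be passed."""
    import inspect

    params = inspect.signature(train).parameters
    assert "masks" not in params and "gt_masks" not in params
    assert list(params) == ["model", "blocks", "boxes_per_block", "cfg"]
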