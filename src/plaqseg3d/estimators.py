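"""scikit-learn-style estimators wrapping the weakly supervised pipeline.

`PlaqueDetector` is the fit/predict face of the 3D detector: ``fit(X, y)``
takes image blocks and their box annotations, ``predict(X)`` returns scored
boxes per block.  `WeaklySupervisedPlaqueSegmenter` adds the PRM + 2D-Otsu
segmentation stage on top and predicts binary masks.  Both compose with
sklearn tooling (``get_params`` / ``set_params`` / ``clone``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import detect3d, prm, segment2dotsu
from .detect3d import AnchorSet, DetectorModel, TrainConfig
from .hrnet3d import HRNetConfig
from .volio import BoundingBox3D, SegmentationMask, VolumeStack

__all__ = ["PlaqueDetector", "WeaklySupervisedPlaqueSegmenter"]


def _block_data(b) -> np.ndarray:
    return b.data if isinstance(b, VolumeStack) else np.asarray(b, np.float32)


class PlaqueDetector(BaseEstimator):
    """Bounding-box-supervised 3D blob detector.

    Parameters mirror the training configuration: the HRNet backbone size,
    the cubic anchor ladder (edges within [6, 28], lattice stride 4) and the
    SGD schedule (lr 0.01, weight decay 1e-4, momentum 0.9).

    Attributes (after ``fit``)
    --------------------------
    model_ : DetectorModel
        The trained backbone + RPN + RoI head.
    loss_history_ : list of float
        Total training loss per iteration.
    """

    def __init__(self, n_branches=3, base_channels=8, n_stages=2,
                 output_mode="hr_fuse",
                 anchor_sizes=detect3d.DEFAULT_ANCHOR_SIZES, anchor_stride=4,
                 lr=0.01, weight_decay=0.0001, momentum=0.9,
                 max_iterations=3000, crop_size=32,
                 score_thresh=0.5, nms_iou=0.3, random_state=0):
        self.n_branches = n_branches
        self.base_channels = base_channels
        self.n_stages = n_stages
        self.output_mode = output_mode
        self.anchor_sizes = anchor_sizes
        self.anchor_stride = anchor_stride
        self.lr = lr
        self.weight_decay = weight_decay
        self.momentum = momentum
        self.max_iterations = max_iterations
        self.crop_size = crop_size
        self.score_thresh = score_thresh
        self.nms_iou = nms_iou
        self.random_state = random_state

    def _configs(self) -> tuple[HRNetConfig, AnchorSet, TrainConfig]:
        bb = HRNetConfig(n_branches=self.n_branches,
                         base_channels=self.base_channels,
                         n_stages=self.n_stages,
                         output_mode=self.output_mode,
                         seed=self.random_state)
        an = AnchorSet(tuple(self.anchor_sizes), self.anchor_stride)
        tc = TrainConfig(lr=self.lr, weight_decay=self.weight_decay,
                         momentum=self.momentum,
                         max_iterations=self.max_iterations,
                         crop_size=self.crop_size, seed=self.random_state)
        return bb, an, tc

    def fit(self, X, y):
        """Train from blocks ``X`` and per-block box lists ``y``."""
        if len(X) != len(y):
            raise ValueError("X and y must have the same length")
        bb, an, tc = self._configs()
        self.model_ = DetectorModel(bb, an, seed=self.random_state)
        history = detect3d.train(self.model_, X, y, tc)
        self.loss_history_ = history["loss"]
        return self

    def predict(self, X) -> list[list[BoundingBox3D]]:
        """Detected boxes (with scores) for each block."""
        self._check_fitted()
        return [detect3d.detect(self.model_, _block_data(b),
                                self.score_thresh, self.nms_iou)[0]
                for b in X]

    def predict_with_rpn(self, block):
        """Detections plus the RPN output (needed by the PRM stage)."""
        self._check_fitted()
        return detect3d.detect(self.model_, _block_data(block),
                               self.score_thresh, self.nms_iou)

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise AttributeError("estimator is not fitted; call fit first")


class WeaklySupervisedPlaqueSegmenter(BaseEstimator):
    """End-to-end weakly supervised segmenter: detector + PRM + 2D-Otsu.

    ``fit`` trains the detector from boxes only; ``predict`` segments blocks
    into binary masks by back-propagating RPN score peaks into
    visiting-probability maps and thresholding the joint (intensity, PRM)
    histogram inside the dilated detection neighbourhood.
    """

    def __init__(self, n_branches=3, base_channels=8, n_stages=2,
                 anchor_sizes=detect3d.DEFAULT_ANCHOR_SIZES,
                 lr=0.01, weight_decay=0.0001, momentum=0.9,
                 max_iterations=3000, crop_size=32,
                 score_thresh=0.5, nms_iou=0.3, bins=64, roi_dilate=4,
                 random_state=0):
        self.n_branches = n_branches
        self.base_channels = base_channels
        self.n_stages = n_stages
        self.anchor_sizes = anchor_sizes
        self.lr = lr
        self.weight_decay = weight_decay
        self.momentum = momentum
        self.max_iterations = max_iterations
        self.crop_size = crop_size
        self.score_thresh = score_thresh
        self.nms_iou = nms_iou
        self.bins = bins
        self.roi_dilate = roi_dilate
        self.random_state = random_state

    def fit(self, X, y):
        self.detector_ = PlaqueDetector(
            n_branches=self.n_branches, base_channels=self.base_channels,
            n_stages=self.n_stages, anchor_sizes=self.anchor_sizes,
            lr=self.lr, weight_decay=self.weight_decay, momentum=self.momentum,
            max_iterations=self.max_iterations, crop_size=self.crop_size,
            score_thresh=self.score_thresh, nms_iou=self.nms_iou,
            random_state=self.random_state,
        ).fit(X, y)
        return self

    def predict(self, X, tissue=None) -> list[SegmentationMask]:
        """Segment each block; optional per-block tissue masks bound the ROI."""
        if not hasattr(self, "detector_"):
            raise AttributeError("estimator is not fitted; call fit first")
        out = []
        for i, b in enumerate(X):
            data = _block_data(b)
            boxes, rpn = self.detector_.predict_with_rpn(data)
            if not boxes:
                out.append(SegmentationMask(np.zeros(data.shape, bool)))
                continue
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                agg, _ = prm.prm_for_block(self.detector_.model_, data, rpn,
                                           score_thresh=self.score_thresh)
            roi = segment2dotsu.detection_roi(
                data.shape, boxes,
                tissue=None if tissue is None else tissue[i],
                dilate=self.roi_dilate,
            )
            if not roi.any() or agg.max() <= 0:
                out.append(SegmentationMask(np.zeros(data.shape, bool)))
                continue
            out.append(segment2dotsu.segment_block(
                data, agg, roi, bins=(self.bins, self.bins)))
        return out
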