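"""3D region-proposal detector trained from bounding boxes only.

A modified Faster-RCNN: the HRNet backbone extracts features, an RPN scores
cubic anchors (edges in [6, 28] voxels, lattice stride 4) and regresses box
deltas, and a small RoI head re-scores and refines proposals pooled with 3D
RoI-Align.  Training consumes image blocks and weak (box) labels exclusively
— no operation in this module accepts a pixel mask.

The RPN objectness map doubles as the peak-correspondence map that the PRM
stage back-propagates, so :func:`detect` returns it alongside the boxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .hrnet3d import HRNet3D, HRNetConfig
from .nn import SGD, Module, Tensor, tape
from .nn.modules import Conv3d
from .nn.tape import Parameter
from .volio import BoundingBox3D, VolumeStack, boxes_to_array, iou_matrix

__all__ = [
    "AnchorSet", "TrainConfig", "RPNOutput", "DetectorModel",
    "generate_anchors", "anchor_array", "assign_targets",
    "encode_boxes", "decode_boxes", "nms3d",
    "train", "detect", "save_checkpoint", "load_checkpoint",
    "TrainingDivergedError", "AnchorRangeWarning",
]

DEFAULT_ANCHOR_SIZES = (6, 10, 14, 20, 28)


class TrainingDivergedError(RuntimeError):
    """Raised when the loss becomes non-finite during training."""


class AnchorRangeWarning(UserWarning):
    """A ground-truth box is far outside the anchor size range."""


@dataclass(frozen=True)
class AnchorSet:
    """Cubic anchors on the RPN feature lattice."""

    sizes: tuple[int, ...] = DEFAULT_ANCHOR_SIZES
    stride: int = 4

    def __post_init__(self) -> None:
        if any(not (6 <= s <= 28) for s in self.sizes):
            raise ValueError(f"anchor sizes must lie in [6, 28], got {self.sizes}")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")

    @property
    def n_sizes(self) -> int:
        return len(self.sizes)


@dataclass
class TrainConfig:
    """SGD training configuration (lr 0.01, weight decay 1e-4, 3000 iters)."""

    lr: float = 0.01
    weight_decay: float = 0.0001
    momentum: float = 0.9
    max_iterations: int = 3000
    seed: int = 0
    iou_pos: float = 0.5
    iou_neg: float = 0.2
    batch_pos: int = 32
    batch_neg: int = 32
    crop_size: int = 32
    rois_per_block: int = 16
    grad_clip: float = 5.0
    log_every: int = 50

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if not self.iou_pos > self.iou_neg:
            raise ValueError("iou_pos must exceed iou_neg")


@dataclass
class RPNOutput:
    """RPN objectness probabilities and box deltas over the feature lattice.

    ``score_map`` is (n_sizes, Zf, Yf, Xf) in [0, 1]; ``score_tensor`` keeps
    the tape node of the pre-sigmoid logits so the PRM stage can walk the
    recorded graph back to the input block.
    """

    score_map: np.ndarray
    box_deltas: np.ndarray
    anchors: AnchorSet
    score_tensor: Tensor | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.score_map)):
            raise ValueError("score map must be finite")


# ---------------------------------------------------------------------------
# anchors and box coding
# ---------------------------------------------------------------------------

def anchor_array(feature_shape: tuple[int, int, int], anchors: AnchorSet) -> np.ndarray:
    """All anchors as an (n_positions * n_sizes, 6) float array.

    Ordering is position-major (lexicographic z, y, x on the lattice),
    size-minor.  Anchors are centred at ``position * stride + stride / 2``
    and are not clipped; detections are clipped at decode time instead.
    """
    st = anchors.stride
    zf, yf, xf = feature_shape
    zz, yy, xx = np.meshgrid(np.arange(zf), np.arange(yf), np.arange(xf),
                             indexing="ij")
    centers = np.stack([zz, yy, xx], axis=-1).reshape(-1, 3) * st + st / 2.0
    sizes = np.asarray(anchors.sizes, dtype=np.float64)
    lo = centers[:, None, :] - sizes[None, :, None] / 2.0
    hi = lo + sizes[None, :, None]
    return np.concatenate([lo, hi], axis=-1).reshape(-1, 6)


def generate_anchors(feature_shape: tuple[int, int, int],
                     anchors: AnchorSet) -> list[BoundingBox3D]:
    """Anchors as :class:`BoundingBox3D` (integer half-open voxel boxes)."""
    arr = anchor_array(feature_shape, anchors)
    out = []
    for row in arr:
        lo = np.floor(row[:3]).astype(int)
        size = (row[3:] - row[:3]).round().astype(int)
        out.append(BoundingBox3D(tuple(lo), tuple(lo + size)))
    return out


def encode_boxes(boxes: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """(center offset / anchor size, log size ratio) regression targets."""
    b, a = np.asarray(boxes, np.float64), np.asarray(anchors, np.float64)
    bc, bs = (b[:, :3] + b[:, 3:]) / 2.0, b[:, 3:] - b[:, :3]
    ac, asz = (a[:, :3] + a[:, 3:]) / 2.0, a[:, 3:] - a[:, :3]
    return np.concatenate([(bc - ac) / asz, np.log(bs / asz)], axis=1)


def decode_boxes(deltas: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    d, a = np.asarray(deltas, np.float64), np.asarray(anchors, np.float64)
    ac, asz = (a[:, :3] + a[:, 3:]) / 2.0, a[:, 3:] - a[:, :3]
    c = ac + d[:, :3] * asz
    s = asz * np.exp(np.clip(d[:, 3:], -6, 6))
    return np.concatenate([c - s / 2.0, c + s / 2.0], axis=1)


def clip_boxes(boxes: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    out = boxes.copy()
    for ax in range(3):
        out[:, ax] = np.clip(out[:, ax], 0, shape[ax])
        out[:, ax + 3] = np.clip(out[:, ax + 3], 0, shape[ax])
    return out


def assign_targets(anchors: np.ndarray, gt_boxes: np.ndarray, cfg: TrainConfig
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Label every anchor pos(1)/neg(0)/ignore(-1) and build regression targets.

    An anchor is positive when its IoU with some ground truth reaches
    ``iou_pos`` or when it is the argmax-IoU anchor of a ground truth (so
    every object owns at least one positive); negative when its best IoU is
    below ``iou_neg``; ignored otherwise.
    """
    import warnings

    n = len(anchors)
    labels = np.full(n, -1, dtype=np.int8)
    matched = np.full(n, -1, dtype=np.int64)
    targets = np.zeros((n, 6), dtype=np.float64)
    if len(gt_boxes) == 0:
        labels[:] = 0
        return labels, matched, targets
    iou = iou_matrix(anchors, gt_boxes)            # (n_anchors, n_gt)
    best = iou.max(axis=1)
    arg = iou.argmax(axis=1)
    labels[best < cfg.iou_neg] = 0
    labels[best >= cfg.iou_pos] = 1
    # force the argmax anchor of each gt positive
    for j in range(iou.shape[1]):
        i = int(iou[:, j].argmax())
        labels[i] = 1
        arg[i] = j
    matched[labels == 1] = arg[labels == 1]
    pos = labels == 1
    targets[pos] = encode_boxes(gt_boxes[arg[pos]], anchors[pos])
    gt_vol = np.prod(gt_boxes[:, 3:] - gt_boxes[:, :3], axis=1)
    if gt_vol.max() > 4.0 * np.prod(anchors[:, 3:] - anchors[:, :3], axis=1).max():
        warnings.warn("anchor range mismatch: a ground-truth box is more than "
                      "4x larger than every anchor", AnchorRangeWarning)
    return labels, matched, targets


def nms3d(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> np.ndarray:
    """Greedy 3D NMS; returns kept indices into the input arrays.

    Candidates are processed by descending score with ties broken by
    lexicographic box coordinates, so the kept set is independent of the
    input ordering.
    """
    if len(boxes) == 0:
        return np.zeros(0, dtype=np.int64)
    order = sorted(range(len(boxes)),
                   key=lambda i: (-scores[i], *boxes[i].tolist()))
    kept: list[int] = []
    for i in order:
        ok = True
        for j in kept:
            lo = np.maximum(boxes[i, :3], boxes[j, :3])
            hi = np.minimum(boxes[i, 3:], boxes[j, 3:])
            inter = np.prod(np.clip(hi - lo, 0, None))
            if inter > 0:
                vi = np.prod(boxes[i, 3:] - boxes[i, :3])
                vj = np.prod(boxes[j, 3:] - boxes[j, :3])
                if inter / (vi + vj - inter) > iou_thresh:
                    ok = False
                    break
        if ok:
            kept.append(i)
    return np.asarray(kept, dtype=np.int64)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class _RPNHead(Module):
    """Stride-4 conv head producing per-anchor objectness and deltas.

    Both intermediate convs are normalised before their ReLU — without this
    the hard-negative pressure on the objectness loss can drive the whole
    head's pre-activations negative, after which dead ReLUs make the score
    map irrecoverably constant.  The scoring convs start near zero
    (std 0.01), the common region-proposal initialisation.

    Objectness is the sum of two paths: a free-sign conv over the learned
    features, and a 1x1 conv over the stride-4 mean-pooled raw intensity.
    The learned path often settles on "anti-evidence" scoring (background
    features weighted negatively) which ranks objects correctly but offers
    no positive-weight transitions for the peak-response walk; the intensity
    path guarantees every peak a positive-evidence route whose walk mass
    flows back onto the bright voxels that caused the detection.
    """

    def __init__(self, cin: int, n_sizes: int, stride: int, rng):
        super().__init__()
        from .nn.modules import BatchNorm3d

        self.stride = stride
        self.reduce = Conv3d(cin, 32, stride, stride=stride, pad=0, rng=rng,
                             bias=False)
        self.norm1 = BatchNorm3d(32)
        self.mid = Conv3d(32, 32, 3, rng=rng, bias=False)
        self.norm2 = BatchNorm3d(32)
        # both scoring convs are bias-free: Eq.-style transitions ignore
        # biases, so a bias inside either branch would make the branch
        # "contribution" negative wherever logits are negative and absorb
        # the walker; one shared per-anchor bias is added afterwards
        self.obj = Conv3d(32, n_sizes, 1, rng=rng, bias=False)
        self.obj.W.data = rng.normal(0, 0.01, self.obj.W.data.shape).astype(np.float32)
        self.reg = Conv3d(32, 6 * n_sizes, 1, rng=rng)
        self.reg.W.data = rng.normal(0, 0.01, self.reg.W.data.shape).astype(np.float32)
        # fixed intensity-evidence pyramid (not trained): stride-4 mean
        # pooling followed by repeated 3^3 lattice means gives per-location
        # mean intensity over ~4/12/20/28-voxel neighbourhoods; each anchor
        # channel reads the level closest to its own box size, so walking a
        # peak back through its evidence spreads mass over an object-sized,
        # intensity-weighted region
        self.pool_W = Tensor(np.full((1, 1, stride, stride, stride),
                                     1.0 / stride ** 3, dtype=np.float32))
        self.mean_W = Tensor(np.full((1, 1, 3, 3, 3), 1.0 / 27, dtype=np.float32))
        self.n_sizes = n_sizes
        self.obj_int = Conv3d(n_sizes, n_sizes, 1, rng=rng, bias=False)
        self.obj_int.W.data = np.eye(n_sizes, dtype=np.float32).reshape(
            n_sizes, n_sizes, 1, 1, 1).copy()
        self.obj_bias = Parameter(np.zeros(n_sizes, dtype=np.float32))

    def _evidence(self, block: Tensor) -> Tensor:
        e = tape.conv3d(block, self.pool_W, None, stride=self.stride, pad=0)
        levels = [e]
        for _ in range(3):
            levels.append(tape.conv3d(levels[-1], self.mean_W, None, 1, 1))
        # anchor edges 6 -> 4-voxel level, 10/14 -> ~12, 20/28 -> ~20
        pick = [0, 1, 1, 2, 2]
        return tape.concat_channels(
            [levels[pick[min(a, len(pick) - 1)]] for a in range(self.n_sizes)])

    def __call__(self, feat: Tensor, block: Tensor) -> tuple[Tensor, Tensor]:
        h = tape.relu(self.norm1(self.reduce(feat)))
        h = tape.relu(self.norm2(self.mid(h)))
        obj = tape.channel_bias(
            tape.add(self.obj(h), self.obj_int(self._evidence(block))),
            self.obj_bias)
        return obj, self.reg(h)


class _RoIHead(Module):
    """RoI-Align 4^3 pooling followed by a two-layer MLP."""

    def __init__(self, cin: int, rng, pool: int = 4, hidden: int = 64):
        super().__init__()
        self.pool = pool
        d = cin * pool ** 3
        self.W1 = Parameter(rng.normal(0, np.sqrt(2.0 / d), (d, hidden)).astype(np.float32))
        self.b1 = Parameter(np.zeros(hidden, dtype=np.float32))
        self.W_cls = Parameter(rng.normal(0, 0.01, (hidden, 1)).astype(np.float32))
        self.b_cls = Parameter(np.zeros(1, dtype=np.float32))
        self.W_reg = Parameter(rng.normal(0, 0.01, (hidden, 6)).astype(np.float32))
        self.b_reg = Parameter(np.zeros(6, dtype=np.float32))

    def __call__(self, feat: Tensor, boxes: np.ndarray) -> tuple[Tensor, Tensor]:
        pooled = tape.roi_align(feat, boxes, self.pool)
        n = pooled.data.shape[0]
        flatten = Tensor(pooled.data.reshape(n, -1),
                         requires_grad=pooled.requires_grad,
                         op=_ReshapeOp(pooled))
        h = tape.relu(tape.linear(flatten, self.W1, self.b1))
        cls = tape.linear(h, self.W_cls, self.b_cls)
        reg = tape.linear(h, self.W_reg, self.b_reg)
        return cls, reg


class _ReshapeOp(tape.Op):
    name = "reshape"

    def __init__(self, x):
        super().__init__((x,))
        self.x = x

    def backward(self, out, grad):
        return [grad.reshape(self.x.data.shape)]


class DetectorModel(Module):
    """Backbone + RPN + RoI head with a single foreground class."""

    def __init__(self, backbone_config: HRNetConfig,
                 anchors: AnchorSet = AnchorSet(), seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed + 1)
        self.backbone = HRNet3D(backbone_config)
        self.anchors = anchors
        self.rpn = _RPNHead(self.backbone.fuse_channels, anchors.n_sizes,
                            anchors.stride, rng)
        self.roi = _RoIHead(self.backbone.fuse_channels, rng)
        self.backbone_config = backbone_config
        self.seed = seed

    def forward_features(self, block: np.ndarray) -> Tensor:
        pyramid = self.backbone.forward(block)
        return self.backbone.fuse_output(pyramid)

    def forward_rpn(self, block: np.ndarray) -> tuple[Tensor, Tensor, Tensor]:
        # one shared leaf tensor feeds both the backbone and the RPN's
        # intensity path, so the peak-response walk ends at a single input
        if not isinstance(block, Tensor):
            block = Tensor(np.asarray(block, np.float32))
        if block.data.ndim == 3:
            block = Tensor(block.data[None])
        pyramid = self.backbone.forward(block)
        feat = self.backbone.fuse_output(pyramid)
        obj, reg = self.rpn(feat, block)
        return feat, obj, reg


# ---------------------------------------------------------------------------
# losses (gradients seeded analytically at the head outputs)
# ---------------------------------------------------------------------------

def _bce_with_logits(logits: np.ndarray, labels: np.ndarray
                     ) -> tuple[float, np.ndarray]:
    z = np.clip(logits, -60, 60)
    p = 1.0 / (1.0 + np.exp(-z))
    loss = float(np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - z * labels))
    grad = (p - labels) / len(labels)
    return loss, grad


def _smooth_l1(pred: np.ndarray, target: np.ndarray, beta: float = 1.0 / 9.0
               ) -> tuple[float, np.ndarray]:
    d = pred - target
    a = np.abs(d)
    loss = np.where(a < beta, 0.5 * d ** 2 / beta, a - 0.5 * beta)
    n = max(pred.shape[0], 1)
    grad = np.where(a < beta, d / beta, np.sign(d)) / n
    return float(loss.sum() / n), grad


def _jitter_boxes(rng, gt: np.ndarray, shape, scale: float = 0.25) -> np.ndarray:
    size = gt[:, 3:] - gt[:, :3]
    shift = rng.uniform(-scale, scale, size=(len(gt), 3)) * size
    grow = np.exp(rng.uniform(-scale, scale, size=(len(gt), 3)))
    c = (gt[:, :3] + gt[:, 3:]) / 2.0 + shift
    s = size * grow
    out = np.concatenate([c - s / 2.0, c + s / 2.0], axis=1)
    return clip_boxes(out, shape)


def _random_boxes(rng, n: int, shape) -> np.ndarray:
    size = rng.uniform(6, 28, size=(n, 3))
    c = rng.uniform(0, 1, size=(n, 3)) * (np.asarray(shape) - 1)
    out = np.concatenate([c - size / 2.0, c + size / 2.0], axis=1)
    out = clip_boxes(out, shape)
    bad = np.any(out[:, 3:] - out[:, :3] < 2, axis=1)
    out[bad, 3:] = out[bad, :3] + 2
    return clip_boxes(out, shape)


def _clip_grad_norm(params, max_norm: float) -> None:
    """Scale all gradients so their global L2 norm is at most ``max_norm``."""
    total = np.sqrt(sum(float(np.sum(p.grad.astype(np.float64) ** 2))
                        for p in params if p.grad is not None))
    if total > max_norm:
        scale = np.float32(max_norm / total)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def train(
    model: DetectorModel,
    blocks: Sequence[np.ndarray | VolumeStack],
    boxes_per_block: Sequence[Sequence[BoundingBox3D]],
    cfg: TrainConfig,
) -> dict:
    """SGD training from weak labels; returns a history dict.

    Each iteration samples one block, cuts a random lattice-aligned cubic
    crop, assigns anchor targets inside the crop, and descends the summed
    RPN objectness (BCE), RPN regression (smooth L1), and RoI head
    classification/regression losses.
    """
    if len(blocks) == 0 or all(len(b) == 0 for b in boxes_per_block):
        raise ValueError("need at least one block with at least one box")
    data = [b.data if isinstance(b, VolumeStack) else np.asarray(b, np.float32)
            for b in blocks]
    gts = [boxes_to_array(bb) for bb in boxes_per_block]
    rng = np.random.default_rng(cfg.seed)
    opt = SGD(model.parameters(), cfg.lr, cfg.momentum, cfg.weight_decay)
    model.train()
    st = model.anchors.stride
    history: list[float] = []

    for it in range(cfg.max_iterations):
        bi = int(rng.integers(len(data)))
        vol, gt = data[bi], gts[bi]
        crop = min(cfg.crop_size, *vol.shape)
        crop -= crop % (2 ** (model.backbone_config.n_branches - 1))
        # lattice-aligned crop origin, biased to contain at least one object
        for _ in range(10):
            o = np.asarray([int(rng.integers(0, (s - crop) // st + 1)) * st
                            if s > crop else 0 for s in vol.shape])
            c = (gt[:, :3] + gt[:, 3:]) / 2.0 if len(gt) else np.zeros((0, 3))
            inside = np.all((c >= o) & (c < o + crop), axis=1) if len(gt) else []
            if len(gt) == 0 or np.any(inside):
                break
        sub = vol[o[0]:o[0] + crop, o[1]:o[1] + crop, o[2]:o[2] + crop]
        sub_gt = gt[inside] - np.tile(o, 2) if len(gt) else gt

        feat, obj, reg = model.forward_rpn(sub)
        fshape = obj.data.shape[1:]
        anchors = anchor_array(fshape, model.anchors)
        labels, matched, targets = assign_targets(anchors, sub_gt, cfg)

        # --- RPN losses: all positives plus a negative batch mixing the
        # hardest (highest-scoring) negatives with random ones, so spurious
        # high scores in the background tail are actively suppressed
        a = model.anchors.n_sizes
        logits_flat = obj.data.transpose(1, 2, 3, 0).reshape(-1)  # pos-major, size-minor
        pos_idx = np.flatnonzero(labels == 1)
        neg_idx = np.flatnonzero(labels == 0)
        if len(pos_idx) > cfg.batch_pos:
            pos_idx = rng.choice(pos_idx, cfg.batch_pos, replace=False)
        n_neg = min(len(neg_idx), max(2 * len(pos_idx), cfg.batch_neg))
        if len(neg_idx) > n_neg:
            hard = neg_idx[np.argsort(-logits_flat[neg_idx], kind="stable")][:n_neg // 2]
            rand = rng.choice(neg_idx, n_neg - len(hard), replace=False)
            neg_idx = np.unique(np.concatenate([hard, rand]))
        batch = np.concatenate([pos_idx, neg_idx])
        blab = np.concatenate([np.ones(len(pos_idx)), np.zeros(len(neg_idx))])
        loss_obj, g = _bce_with_logits(logits_flat[batch], blab)
        g_obj = np.zeros_like(logits_flat)
        g_obj[batch] = g
        g_obj = g_obj.reshape(*fshape, a).transpose(3, 0, 1, 2)

        reg_flat = reg.data.transpose(1, 2, 3, 0).reshape(-1, 6)
        if len(pos_idx):
            loss_reg, gr = _smooth_l1(reg_flat[pos_idx], targets[pos_idx])
        else:
            loss_reg, gr = 0.0, None
        g_reg = np.zeros_like(reg_flat)
        if gr is not None:
            g_reg[pos_idx] = gr
        # invert the (z, y, x, a*6) flattening back to channel-first
        g_reg = np.ascontiguousarray(
            g_reg.reshape(*fshape, 6 * a).transpose(3, 0, 1, 2))

        # --- RoI head on decoded RPN proposals + jittered GT + randoms,
        # so its test-time input distribution is represented
        seeds = [(obj, g_obj), (reg, g_reg)]
        loss_roi = 0.0
        if len(sub_gt):
            n_prop = cfg.rois_per_block
            top = np.argsort(-logits_flat, kind="stable")[:n_prop]
            rpn_props = clip_boxes(
                decode_boxes(reg_flat[top], anchors[top]), sub.shape)
            rpn_props = rpn_props[
                np.all(rpn_props[:, 3:] - rpn_props[:, :3] >= 1, axis=1)]
            props = np.concatenate([
                rpn_props[:n_prop // 2],
                _jitter_boxes(rng, sub_gt, sub.shape),
                _random_boxes(rng, max(2, n_prop // 4), sub.shape),
            ])
            iou = iou_matrix(props, sub_gt)
            roi_lab = (iou.max(axis=1) >= cfg.iou_pos).astype(np.float64)
            roi_arg = iou.argmax(axis=1)
            cls, reg_roi = model.roi(feat, props)
            l_cls, g_cls = _bce_with_logits(cls.data.ravel(), roi_lab)
            seeds.append((cls, g_cls.reshape(cls.data.shape)))
            ppos = np.flatnonzero(roi_lab == 1)
            l_reg = 0.0
            if len(ppos):
                t = encode_boxes(sub_gt[roi_arg[ppos]], props[ppos])
                l_reg, g_rr = _smooth_l1(reg_roi.data[ppos], t)
                g_full = np.zeros_like(reg_roi.data)
                g_full[ppos] = g_rr
                seeds.append((reg_roi, g_full))
            loss_roi = l_cls + l_reg

        total = loss_obj + loss_reg + loss_roi
        if not np.isfinite(total):
            raise TrainingDivergedError(f"non-finite loss at iteration {it}")
        history.append(total)

        opt.zero_grad()
        tape.backward(seeds)
        if cfg.grad_clip > 0:
            _clip_grad_norm(model.parameters(), cfg.grad_clip)
        opt.step()
        # the intensity evidence path must stay non-negative so every peak
        # keeps a walkable positive-weight route to the input (projected
        # SGD step; momentum of clamped entries is reset)
        W_int = model.rpn.obj_int.W
        clamped = W_int.data < 0
        if clamped.any():
            np.maximum(W_int.data, 0.0, out=W_int.data)
            vi = opt.params.index(W_int)
            opt.velocity[vi][clamped] = 0.0

    return {"loss": history}


def detect(
    model: DetectorModel,
    block: np.ndarray | VolumeStack,
    score_thresh: float = 0.5,
    nms_iou: float = 0.3,
    pre_nms: int = 512,
    post_nms: int = 128,
) -> tuple[list[BoundingBox3D], RPNOutput]:
    """Run detection on one block; also returns the RPN output for PRM."""
    vol = block.data if isinstance(block, VolumeStack) else np.asarray(block, np.float32)
    model.eval()
    feat, obj, reg = model.forward_rpn(vol)
    a = model.anchors.n_sizes
    fshape = obj.data.shape[1:]
    scores_map = 1.0 / (1.0 + np.exp(-np.clip(obj.data, -60, 60)))
    rpn_out = RPNOutput(score_map=scores_map, box_deltas=reg.data.copy(),
                        anchors=model.anchors, score_tensor=obj)

    anchors = anchor_array(fshape, model.anchors)
    scores = scores_map.transpose(1, 2, 3, 0).ravel()
    deltas = reg.data.reshape(a, 6, *fshape).transpose(2, 3, 4, 0, 1).reshape(-1, 6)
    # per-channel proposal quotas keep smaller (dimmer) anchor sizes
    # represented even when one bright object dominates the score map
    quota = max(pre_nms // a, 1)
    parts = []
    for c in range(a):
        idx = np.arange(c, len(scores), a)
        top = idx[np.argsort(-scores[idx], kind="stable")[:quota]]
        parts.append(top)
    order = np.concatenate(parts)
    order = order[np.argsort(-scores[order], kind="stable")]
    boxes = clip_boxes(decode_boxes(deltas[order], anchors[order]), vol.shape)
    ok = np.all(boxes[:, 3:] - boxes[:, :3] >= 1, axis=1)
    boxes, psc = boxes[ok], scores[order][ok]
    keep = nms3d(boxes, psc, nms_iou)[:post_nms]
    boxes, psc = boxes[keep], psc[keep]
    if len(boxes) == 0:
        return [], rpn_out

    # the RoI head refines box geometry; with desk-scale training budgets its
    # classifier is under-calibrated, so ranking stays with the RPN score
    cls, reg_roi = model.roi(feat, boxes)
    refined = clip_boxes(decode_boxes(reg_roi.data, boxes), vol.shape)
    final = psc
    sel = final > score_thresh
    boxes, final = refined[sel], final[sel]
    ok = np.all(boxes[:, 3:] - boxes[:, :3] >= 1, axis=1)
    boxes, final = boxes[ok], final[ok]
    keep = nms3d(boxes, final, nms_iou)
    out = []
    for i in keep:
        lo = np.floor(boxes[i, :3]).astype(int)
        hi = np.maximum(np.ceil(boxes[i, 3:]).astype(int), lo + 1)
        lo = np.clip(lo, 0, np.asarray(vol.shape) - 1)
        hi = np.clip(hi, lo + 1, vol.shape)
        out.append(BoundingBox3D(tuple(lo), tuple(hi),
                                 float(np.clip(final[i], 0, 1))))
    return out, rpn_out


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: DetectorModel, path: str | Path) -> Path:
    """Single-file checkpoint with the config embedded."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.named_state()
    meta = {
        "backbone": model.backbone_config.to_dict(),
        "anchor_sizes": list(model.anchors.sizes),
        "anchor_stride": model.anchors.stride,
        "seed": model.seed,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)
    return path if path.suffix == ".npz" else Path(str(path) + ".npz")


def load_checkpoint(path: str | Path) -> DetectorModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    model = DetectorModel(
        HRNetConfig(**meta["backbone"]),
        AnchorSet(tuple(meta["anchor_sizes"]), meta["anchor_stride"]),
        seed=meta["seed"],
    )
    model.load_state(state)
    return model
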