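"""Dynamic-graph tensors with reverse-mode differentiation.

Each forward op records its inputs and parameters on the produced tensor, so
the same graph serves two consumers: gradient back-propagation for SGD
training, and the peak-response random walk, which needs the cached
activations and conv weights of every layer between the score map and the
image.
"""

from __future__ import annotations

import numpy as np

from . import functional as F

__all__ = [
    "Tensor", "Parameter",
    "conv3d", "batchnorm3d", "relu", "add", "upsample_nearest", "sigmoid",
    "linear", "roi_align", "channel_bias", "concat_channels",
    "backward", "topo_order", "receptive_field",
]


class Tensor:
    """A float32 array plus the op that produced it."""

    __slots__ = ("data", "grad", "op", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, op: "Op | None" = None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.op = op
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Op:
    """Base op: holds input tensors and computes input gradients."""

    name = "op"

    def __init__(self, inputs: tuple[Tensor, ...]):
        self.inputs = inputs

    def backward(self, out: Tensor, grad: np.ndarray) -> list[np.ndarray | None]:
        raise NotImplementedError


def _make(data, op: Op) -> Tensor:
    rq = any(t.requires_grad for t in op.inputs)
    return Tensor(data, requires_grad=rq, op=op if rq or True else None)


# ---------------------------------------------------------------------------
# ops
# ---------------------------------------------------------------------------

class ConvOp(Op):
    name = "conv3d"

    def __init__(self, x: Tensor, W: Parameter, b: Parameter | None,
                 stride: int, pad: int):
        super().__init__((x, W) if b is None else (x, W, b))
        self.x, self.W, self.b = x, W, b
        self.stride, self.pad = stride, pad
        self.k = W.data.shape[2]

    def backward(self, out, grad):
        dx = dW = db = None
        g = grad[None] if grad.ndim == 4 else grad
        x4 = self.x.data[None] if self.x.data.ndim == 4 else self.x.data
        if self.x.requires_grad:
            dx = F.conv3d_input_grad(g, self.W.data, self.stride, self.pad,
                                     x4.shape[2:])
            if self.x.data.ndim == 4:
                dx = dx[0]
        if self.W.requires_grad:
            dW, db = F.conv3d_weight_grad(x4, g, self.k, self.stride, self.pad)
        grads = [dx, dW]
        if self.b is not None:
            grads.append(db)
        return grads


def conv3d(x: Tensor, W: Parameter, b: Parameter | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    x4 = x.data[None] if x.data.ndim == 4 else x.data
    y = F.conv3d(x4, W.data, None if b is None else b.data, stride, pad)
    if x.data.ndim == 4:
        y = y[0]
    return _make(y, ConvOp(x, W, b, stride, pad))


class BatchNormOp(Op):
    name = "batchnorm3d"

    def __init__(self, x, gamma, beta, mean, var, eps, training):
        super().__init__((x, gamma, beta))
        self.x, self.gamma, self.beta = x, gamma, beta
        self.mean, self.var, self.eps, self.training = mean, var, eps, training

    def backward(self, out, grad):
        x = self.x.data
        c = x.shape[0]
        axes = (1, 2, 3)
        n = x[0].size
        ivar = (1.0 / np.sqrt(self.var + self.eps)).astype(np.float32)
        xhat = (x - self.mean[:, None, None, None]) * ivar[:, None, None, None]
        dgamma = (grad * xhat).sum(axis=axes)
        dbeta = grad.sum(axis=axes)
        dx = None
        if self.x.requires_grad:
            g = self.gamma.data[:, None, None, None]
            if self.training:
                dxhat = grad * g
                dx = (ivar[:, None, None, None] / n) * (
                    n * dxhat
                    - dxhat.sum(axis=axes, keepdims=True)
                    - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True)
                )
            else:
                dx = grad * g * ivar[:, None, None, None]
        return [dx, dgamma, dbeta]


def batchnorm3d(x: Tensor, gamma: Parameter, beta: Parameter,
                running_mean: np.ndarray, running_var: np.ndarray,
                training: bool, momentum: float = 0.1,
                eps: float = 1e-5) -> Tensor:
    """Per-channel normalisation over the spatial axes of a (C, Z, Y, X) map.

    With single-volume batches the batch statistics are the spatial
    (instance) statistics, and those are used in evaluation as well: running
    averages collected from small biased training crops transfer poorly to
    full test blocks, whereas per-input statistics are deterministic and
    consistent between the two phases.  Running buffers are still maintained
    for inspection.
    """
    d = x.data
    mean = d.mean(axis=(1, 2, 3))
    var = d.var(axis=(1, 2, 3))
    if training:
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    ivar = 1.0 / np.sqrt(var + eps)
    y = (d - mean[:, None, None, None]) * ivar[:, None, None, None]
    y = y * gamma.data[:, None, None, None] + beta.data[:, None, None, None]
    # statistics always derive from x, so backward always uses the full form
    return _make(y, BatchNormOp(x, gamma, beta, mean.astype(np.float32),
                                var.astype(np.float32), eps, True))


class ReluOp(Op):
    name = "relu"

    def __init__(self, x):
        super().__init__((x,))
        self.x = x

    def backward(self, out, grad):
        return [grad * (self.x.data > 0)]


def relu(x: Tensor) -> Tensor:
    return _make(np.maximum(x.data, 0), ReluOp(x))


class AddOp(Op):
    name = "add"

    def __init__(self, a, b):
        super().__init__((a, b))
        self.a, self.b = a, b

    def backward(self, out, grad):
        return [grad, grad]


def add(a: Tensor, b: Tensor) -> Tensor:
    return _make(a.data + b.data, AddOp(a, b))


class UpsampleOp(Op):
    name = "upsample_nearest"

    def __init__(self, x, factor):
        super().__init__((x,))
        self.x, self.factor = x, factor

    def backward(self, out, grad):
        f = self.factor
        c, z, y, x = self.x.data.shape
        g = grad.reshape(c, z, f, y, f, x, f).sum(axis=(2, 4, 6))
        return [g]


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    d = x.data
    y = d.repeat(factor, axis=1).repeat(factor, axis=2).repeat(factor, axis=3)
    return _make(y, UpsampleOp(x, factor))


class ConcatOp(Op):
    name = "concat"

    def __init__(self, xs):
        super().__init__(tuple(xs))
        self.sizes = [t.data.shape[0] for t in xs]

    def backward(self, out, grad):
        grads, start = [], 0
        for c in self.sizes:
            grads.append(grad[start:start + c])
            start += c
        return grads


def concat_channels(xs: list[Tensor]) -> Tensor:
    """Concatenate (C, Z, Y, X) tensors along the channel axis."""
    return _make(np.concatenate([t.data for t in xs], axis=0), ConcatOp(xs))


class ChannelBiasOp(Op):
    name = "channel_bias"

    def __init__(self, x, b):
        super().__init__((x, b))
        self.x, self.b = x, b

    def backward(self, out, grad):
        return [grad, grad.sum(axis=(1, 2, 3))]


def channel_bias(x: Tensor, b: Parameter) -> Tensor:
    """Add a per-channel bias as its own graph node.

    Keeping the bias out of the preceding convolutions matters for the
    peak-response walk: transition probabilities are defined on weights and
    activations only, so the walk treats this op as identity.
    """
    return _make(x.data + b.data[:, None, None, None], ChannelBiasOp(x, b))


class SigmoidOp(Op):
    name = "sigmoid"

    def __init__(self, x):
        super().__init__((x,))
        self.x = x

    def backward(self, out, grad):
        s = out.data
        return [grad * s * (1.0 - s)]


def sigmoid(x: Tensor) -> Tensor:
    d = np.clip(x.data, -60, 60)
    return _make(1.0 / (1.0 + np.exp(-d)), SigmoidOp(x))


class LinearOp(Op):
    name = "linear"

    def __init__(self, x, W, b):
        super().__init__((x, W, b))
        self.x, self.W, self.b = x, W, b

    def backward(self, out, grad):
        dx = grad @ self.W.data.T if self.x.requires_grad else None
        dW = self.x.data.T @ grad
        db = grad.sum(axis=0)
        return [dx, dW, db]


def linear(x: Tensor, W: Parameter, b: Parameter) -> Tensor:
    return _make(x.data @ W.data + b.data, LinearOp(x, W, b))


class RoiAlignOp(Op):
    name = "roi_align"

    def __init__(self, x, idx, wts, out_shape):
        super().__init__((x,))
        self.x, self.idx, self.wts, self.out_shape = x, idx, wts, out_shape

    def backward(self, out, grad):
        if not self.x.requires_grad:
            return [None]
        c, z, y, x = self.x.data.shape
        # grad is (n_boxes, C, b, b, b); flatten bins to match the sample order
        gg = grad.transpose(0, 2, 3, 4, 1).reshape(-1, c)   # (M, C)
        contrib = gg[:, None, :] * self.wts[:, :, None]     # (M, 8, C)
        dxT = np.zeros((z * y * x, c), dtype=np.float32)
        np.add.at(dxT, self.idx.reshape(-1), contrib.reshape(-1, c))
        return [np.ascontiguousarray(dxT.T).reshape(self.x.data.shape)]


def roi_align(x: Tensor, boxes: np.ndarray, out_size: int = 4) -> Tensor:
    """3D RoI-Align with one trilinear sample at each bin centre.

    ``boxes`` is (n, 6) float ``(z0, y0, x0, z1, y1, x1)`` in the coordinate
    frame of ``x`` (C, Z, Y, X).  Returns (n, C, out, out, out).
    """
    c, Z, Y, X = x.data.shape
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 6)
    n = len(boxes)
    b = out_size
    # bin-centre sample coordinates per axis: lo + (i + .5) * extent / b - .5
    coords = []
    for ax, size in zip(range(3), (Z, Y, X)):
        lo, hi = boxes[:, ax], boxes[:, ax + 3]
        step = (hi - lo) / b
        cc = lo[:, None] + (np.arange(b) + 0.5) * step[:, None] - 0.5
        coords.append(np.clip(cc, 0.0, size - 1.0))
    zc = coords[0][:, :, None, None]
    yc = coords[1][:, None, :, None]
    xc = coords[2][:, None, None, :]
    zc, yc, xc = np.broadcast_arrays(zc + 0 * yc + 0 * xc, yc + 0 * zc + 0 * xc,
                                     xc + 0 * zc + 0 * yc)
    pts = np.stack([zc.ravel(), yc.ravel(), xc.ravel()], axis=1)  # (n*b^3, 3)
    lo = np.floor(pts).astype(np.int64)
    hi = np.minimum(lo + 1, [Z - 1, Y - 1, X - 1])
    frac = (pts - lo).astype(np.float32)
    corners = []
    weights = []
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                iz = np.where(dz, hi[:, 0], lo[:, 0])
                iy = np.where(dy, hi[:, 1], lo[:, 1])
                ix = np.where(dx, hi[:, 2], lo[:, 2])
                w = (np.where(dz, frac[:, 0], 1 - frac[:, 0])
                     * np.where(dy, frac[:, 1], 1 - frac[:, 1])
                     * np.where(dx, frac[:, 2], 1 - frac[:, 2]))
                corners.append((iz * Y + iy) * X + ix)
                weights.append(w)
    idx = np.stack(corners, axis=1)                  # (M, 8)
    wts = np.stack(weights, axis=1).astype(np.float32)
    flat = x.data.reshape(c, -1)
    vals = flat[:, idx]                              # (C, M, 8)
    out = (vals * wts[None]).sum(axis=2)             # (C, M)
    out = out.T.reshape(n, b, b, b, c).transpose(0, 4, 1, 2, 3)
    return _make(np.ascontiguousarray(out), RoiAlignOp(x, idx, wts, (n, c, b, b, b)))


# ---------------------------------------------------------------------------
# graph traversal
# ---------------------------------------------------------------------------

def topo_order(roots: "Tensor | list[Tensor]") -> list[Tensor]:
    """Tensors ordered so every tensor precedes all of its op inputs."""
    if isinstance(roots, Tensor):
        roots = [roots]
    seen: set[int] = set()
    post: list[Tensor] = []

    for root in roots:
        stack: list[tuple[Tensor, bool]] = [(root, False)]
        while stack:
            t, done = stack.pop()
            if done:
                post.append(t)
                continue
            if id(t) in seen:
                continue
            seen.add(id(t))
            stack.append((t, True))
            if t.op is not None:
                for child in t.op.inputs:
                    stack.append((child, False))
    return list(reversed(post))


def backward(seeds: list[tuple[Tensor, np.ndarray]]) -> None:
    """Accumulate gradients from ``(tensor, d_loss/d_tensor)`` seeds."""
    roots = [t for t, _ in seeds]
    grads: dict[int, np.ndarray] = {}
    for t, g in seeds:
        g = np.asarray(g, dtype=np.float32)
        if g.shape != t.data.shape:
            raise ValueError("seed gradient shape mismatch")
        grads[id(t)] = grads.get(id(t), 0) + g
    for t in topo_order(roots):
        g = grads.pop(id(t), None)
        if g is None:
            continue
        if t.requires_grad and t.op is None:
            t.grad = g if t.grad is None else t.grad + g
            continue
        if t.op is None:
            continue
        in_grads = t.op.backward(t, g)
        for child, cg in zip(t.op.inputs, in_grads):
            if cg is None or not child.requires_grad:
                continue
            if id(child) in grads:
                grads[id(child)] = grads[id(child)] + cg
            else:
                grads[id(child)] = cg


# ---------------------------------------------------------------------------
# receptive fields
# ---------------------------------------------------------------------------

def receptive_field(out_t: Tensor, in_t: Tensor,
                    loc: tuple[int, int, int]) -> tuple[tuple[int, int], ...] | None:
    """Closed voxel interval of ``in_t`` that can influence ``out_t[..., loc]``.

    Returns per-axis ``(lo, hi)`` inclusive bounds (clipped to the input
    extent), or None when ``out_t`` does not depend on ``in_t``.
    """
    spatial = in_t.data.shape[-3:]

    def rec(t: Tensor, box: list[tuple[int, int]]):
        if t is in_t:
            clipped = []
            for (lo, hi), s in zip(box, spatial):
                lo, hi = max(lo, 0), min(hi, s - 1)
                if hi < lo:
                    return None
                clipped.append((lo, hi))
            return tuple(clipped)
        if t.op is None:
            return None
        op = t.op
        results = []
        if op.name == "conv3d":
            k, s, p = op.k, op.stride, op.pad
            nb = [(lo * s - p, hi * s - p + k - 1) for lo, hi in box]
            results.append(rec(op.x, nb))
        elif op.name in ("relu", "batchnorm3d", "sigmoid", "channel_bias"):
            results.append(rec(op.inputs[0], list(box)))
        elif op.name == "add":
            results.append(rec(op.a, list(box)))
            results.append(rec(op.b, list(box)))
        elif op.name == "concat":
            for child in op.inputs:
                results.append(rec(child, list(box)))
        elif op.name == "upsample_nearest":
            f = op.factor
            nb = [(lo // f, hi // f) for lo, hi in box]
            results.append(rec(op.x, nb))
        else:
            raise ValueError(f"receptive_field: unsupported op {op.name!r}")
        results = [r for r in results if r is not None]
        if not results:
            return None
        lo = [min(r[a][0] for r in results) for a in range(3)]
        hi = [max(r[a][1] for r in results) for a in range(3)]
        return tuple((l, h) for l, h in zip(lo, hi))

    z, y, x = loc
    return rec(out_t, [(z, z), (y, y), (x, x)])
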