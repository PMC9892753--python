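"""Raw batched 3D convolution kernels (tap-slab im2col + BLAS matmul).

Arrays keep their floating dtype (float32 in training, float64 in the
peak-response walk), layout ``(B, C, Z, Y, X)``.  The column matrix is built
as ``(B, C * k^3, N)`` with one cheap strided slab copy per kernel tap, so
the heavy lifting stays inside GEMM.  The same three primitives serve the
forward pass, gradient back-propagation, and the peak-response random walk
(which needs a plain transposed convolution).  Kernels are cubic (k, k, k).
"""

from __future__ import annotations

import numpy as np

__all__ = ["conv3d", "conv3d_input_grad", "conv3d_weight_grad", "conv_out_shape"]


def conv_out_shape(in_shape, k: int, stride: int, pad: int) -> tuple[int, int, int]:
    return tuple((s + 2 * pad - k) // stride + 1 for s in in_shape)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int
            ) -> tuple[np.ndarray, tuple[int, int, int]]:
    """(B, C, Z, Y, X) -> (B, C * k^3, Zo * Yo * Xo), plus the output shape."""
    b, c = x.shape[:2]
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    zo, yo, xo = conv_out_shape(x.shape[2:], k, 1, 0) if stride == 1 else \
        tuple((s - k) // stride + 1 for s in x.shape[2:])
    cols = np.empty((b, c, k, k, k, zo, yo, xo), dtype=x.dtype)
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                cols[:, :, dz, dy, dx] = x[
                    :, :,
                    dz:dz + (zo - 1) * stride + 1:stride,
                    dy:dy + (yo - 1) * stride + 1:stride,
                    dx:dx + (xo - 1) * stride + 1:stride,
                ]
    return cols.reshape(b, c * k ** 3, zo * yo * xo), (zo, yo, xo)


#: column matrices above this size fall back to the tap-loop path
_COLS_BYTE_LIMIT = 512 * 1024 ** 2


def conv3d(x: np.ndarray, W: np.ndarray, bias: np.ndarray | None = None,
           stride: int = 1, pad: int = 0) -> np.ndarray:
    """Cross-correlation of ``x`` (B, Cin, *S) with ``W`` (Cout, Cin, k, k, k)."""
    bsz = x.shape[0]
    co, ci, k = W.shape[0], W.shape[1], W.shape[2]
    dtype = np.result_type(x.dtype, W.dtype)
    xs = x.astype(dtype, copy=False)
    Wm = W.reshape(co, ci * k ** 3).astype(dtype, copy=False)
    if pad:
        xs = np.pad(xs, ((0, 0), (0, 0), (pad, pad), (pad, pad), (pad, pad)))
    out_shape = tuple((s - k) // stride + 1 for s in xs.shape[2:])
    n = int(np.prod(out_shape))
    cols_bytes = bsz * ci * k ** 3 * n * dtype.itemsize
    if cols_bytes <= _COLS_BYTE_LIMIT:
        cols, out_shape = _im2col(xs, k, stride, 0)
        y = np.matmul(Wm, cols)
    else:
        # accumulate one GEMM per kernel tap; transient memory stays O(input)
        y = np.zeros((bsz, co, n), dtype=dtype)
        zo, yo, xo = out_shape
        Wt = Wm.reshape(co, ci, k, k, k)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    slab = np.ascontiguousarray(xs[
                        :, :,
                        dz:dz + (zo - 1) * stride + 1:stride,
                        dy:dy + (yo - 1) * stride + 1:stride,
                        dx:dx + (xo - 1) * stride + 1:stride,
                    ]).reshape(bsz, ci, n)
                    y += np.matmul(Wt[:, :, dz, dy, dx], slab)
    if bias is not None:
        y += bias.astype(dtype, copy=False)[:, None]
    return y.reshape(bsz, co, *out_shape)


def conv3d_input_grad(dy: np.ndarray, W: np.ndarray, stride: int, pad: int,
                      in_spatial: tuple[int, int, int]) -> np.ndarray:
    """Gradient w.r.t. the conv input; equals the transposed convolution.

    ``dy`` is (B, Cout, Zo, Yo, Xo); returns (B, Cin, *in_spatial).
    """
    b, co = dy.shape[:2]
    k = W.shape[2]
    out_spatial = dy.shape[2:]
    if stride == k and pad == 0:
        # non-overlapping taps: each input voxel receives from exactly one
        # output cell; a tensordot avoids the dilated-buffer blow-up
        ci = W.shape[1]
        tmp = np.tensordot(dy, W, axes=([1], [0]))   # (B, *out, Ci, k, k, k)
        tmp = tmp.transpose(0, 4, 1, 5, 2, 6, 3, 7)  # (B, Ci, Zo, k, Yo, k, Xo, k)
        full = tmp.reshape(b, ci, *(o * k for o in out_spatial))
        out = np.zeros((b, ci, *in_spatial), dtype=full.dtype)
        sl = tuple(slice(0, min(o * k, s)) for o, s in zip(out_spatial, in_spatial))
        out[(slice(None), slice(None), *sl)] = full[(slice(None), slice(None), *sl)]
        return out
    # dilate by the stride, then pad so a stride-1 valid conv with the
    # flipped kernel reproduces the input extent (right side absorbs the
    # remainder lost by integer division in the forward pass)
    dil = [(o - 1) * stride + 1 for o in out_spatial]
    rem = [s + 2 * pad - k - stride * (o - 1)
           for s, o in zip(in_spatial, out_spatial)]
    buf = np.zeros((b, co, *dil), dtype=np.result_type(dy.dtype, W.dtype))
    buf[:, :, ::stride, ::stride, ::stride] = dy
    pads = [(k - 1 - pad, k - 1 - pad + r) for r in rem]
    buf = np.pad(buf, ((0, 0), (0, 0), *pads))
    Wt = np.ascontiguousarray(W[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
    return conv3d(buf, Wt, None, stride=1, pad=0)


def conv3d_weight_grad(x: np.ndarray, dy: np.ndarray, k: int, stride: int,
                       pad: int) -> tuple[np.ndarray, np.ndarray]:
    """Gradients w.r.t. weights (Cout, Cin, k, k, k) and bias (Cout,)."""
    ci = x.shape[1]
    co = dy.shape[1]
    cols, _ = _im2col(x, k, stride, pad)               # (B, Ci*k^3, N)
    dy_mat = dy.reshape(dy.shape[0], co, -1)           # (B, Co, N)
    dW = np.matmul(dy_mat, cols.transpose(0, 2, 1)).sum(axis=0)
    db = dy_mat.sum(axis=(0, 2))
    return dW.reshape(co, ci, k, k, k), db
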