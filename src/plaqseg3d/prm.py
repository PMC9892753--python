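"""Peak stimulation and probabilistic peak back-propagation.

Peaks (strict local maxima) of the RPN objectness map are strong visual cues
for object centres.  Each peak is back-propagated to input resolution as a
random walk: a unit of "walker mass" starts at the peak and flows backwards
layer by layer.  For a conv layer with cached bottom-up activations ``I_hat``
and weights ``W``, the probability of stepping from output location ``O_pqt``
to input location ``I_ijk`` is

    P(I_ijk | O_pqt) = Z_pqt * I_hat_ijk * ReLU(W_(i-p)(j-q)(k-t))

with ``Z_pqt`` normalising the admissible inputs of each output location to
probability one; negative weights and zero activations are excluded.  The
visiting probability of an input location is the sum over output locations of
transition probability times the output's own visiting probability.  Output
locations with no admissible input (undefined ``Z``) absorb their mass; the
absorbed total is tracked and reported so conservation can always be checked.

Batch-norm layers (evaluation mode) are folded into the adjacent convolution
before the transition is computed; ReLU and sigmoid are monotone elementwise
maps and pass mass through unchanged; sums (skip connections and fusion)
split mass across branches proportionally to each branch's non-negative
contribution; nearest-neighbour upsampling routes mass to its unique source
voxel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .nn import functional as F
from .nn.tape import Tensor, topo_order

__all__ = [
    "Peak", "TransitionKernel", "PeakResponseMap",
    "find_peaks", "transition_probabilities",
    "backpropagate_peak", "backpropagate_peaks", "prm_for_block",
    "UncachedActivationsError",
]


class UncachedActivationsError(RuntimeError):
    """PRM was asked to walk a graph without cached forward activations."""


@dataclass(frozen=True)
class Peak:
    """A strict local maximum of the score map."""

    location: tuple[int, int, int]
    channel: int
    value: float


@dataclass
class TransitionKernel:
    """One conv layer's ingredients for Eq.-style transition probabilities.

    ``weights`` is the (possibly BN-folded) filter, ``activations`` the
    cached bottom-up input map, both single-channel arrays of matching
    dimensionality.
    """

    weights: np.ndarray
    activations: np.ndarray
    stride: int = 1
    pad: int = 0


@dataclass
class PeakResponseMap:
    """Visiting probabilities of input voxels for one peak."""

    prob: np.ndarray
    peak: Peak
    absorbed_mass: float = 0.0

    @property
    def total_mass(self) -> float:
        return float(self.prob.sum())


# ---------------------------------------------------------------------------
# peak stimulation
# ---------------------------------------------------------------------------

def find_peaks(score_map: np.ndarray, window: int = 3,
               min_score: float = 0.0) -> list[Peak]:
    """Strict window-maxima of a (C, Z, Y, X) or (Z, Y, X) score map.

    Returned peaks are sorted by descending value, ties broken by
    lexicographic (channel, z, y, x).  Constant plateaus yield no peaks.
    """
    sm = np.asarray(score_map, dtype=np.float64)
    if not np.all(np.isfinite(sm)):
        raise ValueError("score map must be finite")
    squeeze = sm.ndim == 3
    if squeeze:
        sm = sm[None]
    footprint = np.ones((window,) * 3, dtype=bool)
    footprint[(window // 2,) * 3] = False
    peaks: list[Peak] = []
    for c in range(sm.shape[0]):
        neigh = ndimage.maximum_filter(sm[c], footprint=footprint,
                                       mode="constant", cval=-np.inf)
        hit = (sm[c] > neigh) & (sm[c] >= min_score)
        for z, y, x in np.argwhere(hit):
            peaks.append(Peak((int(z), int(y), int(x)), 0 if squeeze else c,
                              float(sm[c, z, y, x])))
    peaks.sort(key=lambda p: (-p.value, p.channel, *p.location))
    return peaks


# ---------------------------------------------------------------------------
# single-layer transitions (reference API for the formulas)
# ---------------------------------------------------------------------------

def transition_probabilities(layer: TransitionKernel,
                             output_loc: tuple[int, ...]) -> dict[tuple[int, ...], float]:
    """Transition probabilities from one output location to its inputs.

    Probabilities are proportional to ``activation * ReLU(weight)`` over the
    filter support and normalised to sum to one.  When every candidate
    product is zero the normaliser is undefined and an empty map is returned
    (the walker mass at that location is absorbed).
    """
    W = np.asarray(layer.weights, dtype=np.float64)
    act = np.asarray(layer.activations, dtype=np.float64)
    if W.ndim != act.ndim:
        raise ValueError("weights and activations must share dimensionality")
    out: dict[tuple[int, ...], float] = {}
    weights_pos = np.maximum(W, 0.0)
    for tap in np.ndindex(*W.shape):
        in_loc = tuple(int(o) * layer.stride - layer.pad + t
                       for o, t in zip(output_loc, tap))
        if any(i < 0 or i >= s for i, s in zip(in_loc, act.shape)):
            continue
        p = max(float(act[in_loc]), 0.0) * float(weights_pos[tap])
        if p > 0:
            out[in_loc] = out.get(in_loc, 0.0) + p
    total = sum(out.values())
    if total <= 0:
        return {}
    return {k: v / total for k, v in out.items()}


# ---------------------------------------------------------------------------
# full-graph walk
# ---------------------------------------------------------------------------

def _conv_transition(op, mass: np.ndarray, scale: np.ndarray | None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Move batched mass (P, Cout, *) through a conv to (P, Cin, *)."""
    x = op.x.data
    if x is None:
        raise UncachedActivationsError("run a forward pass before PRM")
    x4 = x[None] if x.ndim == 4 else x
    dtype = mass.dtype
    W = op.W.data.astype(dtype)
    if scale is not None:
        W = W * scale[:, None, None, None, None].astype(dtype)
    Wp = np.maximum(W, 0)
    xp = np.maximum(x4.astype(dtype), 0)
    denom = F.conv3d(xp, Wp, None, op.stride, op.pad)   # (1, Cout, *)
    admissible = denom > 0
    ratio = np.where(admissible, mass / np.where(admissible, denom, 1), 0).astype(dtype)
    absorbed = np.where(admissible, 0, mass).sum(axis=(1, 2, 3, 4), dtype=np.float64)
    out = xp * F.conv3d_input_grad(ratio, Wp, op.stride, op.pad, x4.shape[2:])
    return out, absorbed


def _add_transition(op, mass: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a = np.maximum(op.a.data.astype(mass.dtype), 0)
    b = np.maximum(op.b.data.astype(mass.dtype), 0)
    tot = a + b
    ok = tot > 0
    safe = np.where(ok, tot, 1.0)
    ma = np.where(ok, mass * (a / safe), 0)
    mb = np.where(ok, mass * (b / safe), 0)
    absorbed = np.where(ok, 0, mass).sum(axis=(1, 2, 3, 4), dtype=np.float64)
    return ma, mb, absorbed


def _upsample_transition(op, mass: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = op.factor
    p = mass.shape[0]
    c, z, y, x = op.x.data.shape
    pooled = mass.reshape(p, c, z, f, y, f, x, f).sum(axis=(3, 5, 7))
    ok = op.x.data > 0
    out = np.where(ok[None], pooled, 0)
    absorbed = np.where(ok[None], 0, pooled).sum(axis=(1, 2, 3, 4), dtype=np.float64)
    return out, absorbed


def _bn_scale(op) -> np.ndarray:
    return op.gamma.data.astype(np.float64) / np.sqrt(op.var.astype(np.float64) + op.eps)


def _walk(root: Tensor, init_mass: np.ndarray
          ) -> tuple[dict[int, np.ndarray], np.ndarray]:
    """Propagate batched walker mass from ``root`` down to the graph leaves.

    Returns mass accumulated at leaf tensors (keyed by id) and the absorbed
    mass per batch element.
    """
    n_batch = init_mass.shape[0]
    order = topo_order(root)
    mass: dict[int, np.ndarray] = {id(root): init_mass}
    scales: dict[int, np.ndarray] = {}
    absorbed = np.zeros(n_batch, dtype=np.float64)
    leaves: dict[int, np.ndarray] = {}

    def deposit(t: Tensor, m: np.ndarray) -> None:
        key = id(t)
        if key in mass:
            mass[key] = mass[key] + m
        else:
            mass[key] = m

    for t in order:
        m = mass.pop(id(t), None)
        if m is None:
            continue
        if not np.any(m):
            continue  # nothing to propagate along this branch
        op = t.op
        if op is None:
            if id(t) in leaves:
                leaves[id(t)] += m
            else:
                leaves[id(t)] = m
            continue
        name = op.name
        if name == "conv3d":
            out, ab = _conv_transition(op, m, scales.pop(id(t), None))
            absorbed += ab
            deposit(op.x, out)
        elif name == "batchnorm3d":
            deposit(op.x, m)
            s = _bn_scale(op)
            prev = scales.get(id(op.x))
            scales[id(op.x)] = s if prev is None else s * prev
        elif name in ("relu", "sigmoid", "channel_bias"):
            deposit(op.inputs[0], m)
        elif name == "concat":
            start = 0
            for child, c in zip(op.inputs, op.sizes):
                deposit(child, m[:, start:start + c])
                start += c
        elif name == "add":
            ma, mb, ab = _add_transition(op, m)
            absorbed += ab
            deposit(op.a, ma)
            deposit(op.b, mb)
        elif name == "upsample_nearest":
            out, ab = _upsample_transition(op, m)
            absorbed += ab
            deposit(op.x, out)
        else:
            raise ValueError(f"peak back-propagation does not support op {name!r}")
    return leaves, absorbed


def _input_leaf(root: Tensor) -> Tensor:
    """The non-parameter leaf (the image block) the walk should end at."""
    leaves = [t for t in topo_order(root) if t.op is None and not t.requires_grad]
    if not leaves:
        raise UncachedActivationsError(
            "no input leaf found; run the model forward pass first"
        )
    # the image is the unique non-parameter leaf in detector graphs
    return max(leaves, key=lambda t: t.data.size)


#: graphs whose input exceeds this many voxels walk in float32
_FLOAT64_VOXEL_LIMIT = 64 ** 3 // 4


def backpropagate_peaks(root: Tensor, peaks: list[Peak], chunk: int = 8,
                        dtype=None) -> list[PeakResponseMap]:
    """Walk several peaks through one cached graph, batched in chunks.

    All peaks share the forward activations and per-layer normalisers, so the
    walk is linear in its initial mass and batches cheaply; chunking bounds
    the memory of the batched mass fields on large blocks.  Small graphs walk
    in float64 (mass balances close to machine precision, matching the
    transition-matrix oracle); production-size blocks use float32, whose
    ~1e-7 per-layer rounding is negligible against the 2D-Otsu binning.
    """
    if not peaks:
        return []
    leaf = _input_leaf(root)
    if dtype is None:
        dtype = np.float64 if leaf.data.size <= _FLOAT64_VOXEL_LIMIT else np.float32
    maps: list[PeakResponseMap] = []
    for lo in range(0, len(peaks), chunk):
        part = peaks[lo:lo + chunk]
        init = np.zeros((len(part), *root.data.shape), dtype=dtype)
        for i, p in enumerate(part):
            init[(i, p.channel, *p.location)] = 1.0
        leaves, absorbed = _walk(root, init)
        got = leaves.get(id(leaf))
        if got is None:
            got = np.zeros((len(part), *leaf.data.shape))
        for i, p in enumerate(part):
            prob = got[i].sum(axis=0)  # collapse input channels
            maps.append(PeakResponseMap(prob=prob, peak=p,
                                        absorbed_mass=float(absorbed[i])))
    return maps


def backpropagate_peak(root: Tensor, peak: Peak) -> PeakResponseMap:
    """Visiting-probability map of one score-map peak at input resolution."""
    return backpropagate_peaks(root, [peak])[0]


def _dedupe_peaks(peaks: list[Peak]) -> list[Peak]:
    """One peak per spatial location (anchor channels of one object peak
    together; the highest-scoring channel carries the walk)."""
    seen: set[tuple[int, int, int]] = set()
    out = []
    for p in peaks:  # already sorted by descending value
        if p.location not in seen:
            seen.add(p.location)
            out.append(p)
    return out


def prm_for_block(model, block, detections_or_rpn, score_thresh: float = 0.5,
                  window: int = 3, max_peaks: int = 64
                  ) -> tuple[np.ndarray, list[PeakResponseMap]]:
    """Aggregate PRM for a block: per-voxel max over per-peak maps in [0, 1].

    ``detections_or_rpn`` is the :class:`~plaqseg3d.detect3d.RPNOutput`
    returned by ``detect`` on the same block (its ``score_tensor`` anchors
    the cached graph).  Peaks sharing a spatial location across anchor
    channels are walked once.  With no peaks, an all-zero map is returned
    with a warning.
    """
    rpn = detections_or_rpn
    if rpn.score_tensor is None:
        raise UncachedActivationsError("RPNOutput lacks the cached score tensor")
    block_shape = (block.data.shape if hasattr(block, "data")
                   else np.asarray(block).shape)
    peaks = find_peaks(rpn.score_map, window=window, min_score=score_thresh)
    peaks = _dedupe_peaks(peaks)[:max_peaks]
    if not peaks:
        warnings.warn("no peaks above threshold; PRM aggregate is all-zero")
        return np.zeros(block_shape, dtype=np.float64), []
    maps = backpropagate_peaks(rpn.score_tensor, peaks)
    agg = np.max(np.stack([m.prob for m in maps]), axis=0)
    top = agg.max()
    if top > 0:
        agg = agg / top
    return agg, maps
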