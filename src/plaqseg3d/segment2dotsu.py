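"""Final segmentation: 2D-Otsu thresholding on the joint (intensity, PRM)
histogram, applied per block, then montage into the whole-volume mask.

Instead of the handcrafted local-average second feature of classic 2D-Otsu,
the second histogram axis is the peak-response map, which concentrates
probability mass on the most informative voxels of each detected object.
Foreground is the high/high quadrant (intensity bin > t_i AND prm bin >
t_p); the two mixed quadrants are treated as noise and excluded from the
between-class criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .preprocess import BlockGrid
from .volio import SegmentationMask, VolumeStack

__all__ = [
    "JointHistogram", "ThresholdPair", "DegenerateHistogramError",
    "joint_histogram", "otsu2d_threshold", "otsu1d", "segment_block", "montage",
]


class DegenerateHistogramError(ValueError):
    """No threshold pair separates two classes."""


@dataclass
class JointHistogram:
    """Counts over intensity x PRM bins, both axes uniform on [0, 1]."""

    counts: np.ndarray
    intensity_edges: np.ndarray
    prm_edges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ThresholdPair:
    """Bin-index thresholds: foreground is (i > t_intensity, p > t_prm)."""

    t_intensity: int
    t_prm: int
    objective_value: float


def _bin_indices(values: np.ndarray, n_bins: int) -> np.ndarray:
    idx = np.floor(np.clip(values, 0.0, 1.0) * n_bins).astype(np.int64)
    return np.minimum(idx, n_bins - 1)


def joint_histogram(block: VolumeStack | np.ndarray, prm_map: np.ndarray,
                    bins: tuple[int, int] = (64, 64),
                    roi: np.ndarray | SegmentationMask | None = None
                    ) -> JointHistogram:
    """Joint histogram of (intensity, PRM) over the ROI voxels."""
    data = block.data if isinstance(block, VolumeStack) else np.asarray(block)
    prm_map = np.asarray(prm_map)
    if data.shape != prm_map.shape:
        raise ValueError("block and PRM map must share a shape")
    bi, bp = bins
    if bi < 2 or bp < 2:
        raise ValueError("need at least 2 bins per axis")
    if roi is not None:
        r = roi.data if isinstance(roi, SegmentationMask) else np.asarray(roi, bool)
        if not r.any():
            raise ValueError("empty ROI")
        vals_i, vals_p = data[r], prm_map[r]
    else:
        vals_i, vals_p = data.ravel(), prm_map.ravel()
    ii = _bin_indices(vals_i, bi)
    pp = _bin_indices(vals_p, bp)
    counts = np.zeros((bi, bp), dtype=np.int64)
    np.add.at(counts, (ii, pp), 1)
    return JointHistogram(counts,
                          np.linspace(0, 1, bi + 1), np.linspace(0, 1, bp + 1))


def _quadrant_stats(counts: np.ndarray):
    """Integral images of mass and first moments for O(1) quadrant sums."""
    bi, bp = counts.shape
    i_idx = np.arange(bi, dtype=np.float64)[:, None]
    p_idx = np.arange(bp, dtype=np.float64)[None, :]
    c = counts.astype(np.float64)
    cum = lambda a: a.cumsum(axis=0).cumsum(axis=1)
    return cum(c), cum(c * i_idx), cum(c * p_idx)


def otsu2d_threshold(h: JointHistogram) -> ThresholdPair:
    """Maximise the between-class scatter of the two diagonal quadrants.

    For a threshold pair ``(t_i, t_p)`` let the background class be the bins
    ``(<= t_i, <= t_p)`` and the foreground class ``(> t_i, > t_p)`` with
    masses ``n0, n1`` and mean bin vectors ``mu0, mu1``; the objective is the
    trace-of-scatter form ``(n0 * n1 / N^2) * ||mu0 - mu1||^2`` with N the
    total histogram mass.  The search is vectorised over every threshold
    pair and is exactly equivalent to exhaustive search; ties are broken by
    the smallest ``t_intensity``, then smallest ``t_prm``.

    A histogram whose PRM (or intensity) marginal occupies a single bin
    carries no 2D information; it degenerates to classic 1D Otsu on the
    informative marginal, with the degenerate axis threshold set just below
    its occupied bin so all mass lands in the foreground quadrant.
    """
    counts = np.asarray(h.counts)
    if (counts < 0).any():
        raise ValueError("histogram counts must be non-negative")
    nz = np.argwhere(counts > 0)
    if len(nz) < 2:
        raise DegenerateHistogramError("no threshold separates classes")
    occupied_i = np.unique(nz[:, 0])
    occupied_p = np.unique(nz[:, 1])
    if len(occupied_p) == 1:
        t_i, obj = otsu1d(counts.sum(axis=1))
        return ThresholdPair(t_i, max(int(occupied_p[0]) - 1, 0), obj)
    if len(occupied_i) == 1:
        t_p, obj = otsu1d(counts.sum(axis=0))
        return ThresholdPair(max(int(occupied_i[0]) - 1, 0), t_p, obj)

    bi, bp = counts.shape
    n_total = counts.sum()
    m, mi, mp = _quadrant_stats(counts)
    # background quadrant sums at (t_i, t_p) are just the integral images;
    # foreground quadrant sums follow by inclusion-exclusion with the totals
    n0 = m
    si0, sp0 = mi, mp
    n1 = n_total - m[-1:, :] - m[:, -1:] + m
    si1 = mi[-1, -1] - mi[-1:, :] - mi[:, -1:] + mi
    sp1 = mp[-1, -1] - mp[-1:, :] - mp[:, -1:] + mp
    valid = (n0 > 0) & (n1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_i = si1 / n1 - si0 / n0
        d_p = sp1 / n1 - sp0 / n0
        obj = np.where(valid, n0 * n1 / float(n_total) ** 2
                       * (d_i ** 2 + d_p ** 2), -np.inf)
    # last row/column leave one class empty by construction; exclude
    obj[-1, :] = -np.inf
    obj[:, -1] = -np.inf
    best = float(np.nanmax(obj))
    if not np.isfinite(best) or best <= 0:
        raise DegenerateHistogramError("no threshold separates classes")
    ti, tp = np.argwhere(obj == best)[0]  # argwhere is lexicographic
    return ThresholdPair(int(ti), int(tp), best)


def otsu1d(marginal: np.ndarray) -> tuple[int, float]:
    """Classic 1D Otsu on a histogram; returns (threshold bin, objective).

    Foreground is bins strictly above the returned index; the objective is
    ``w0 * w1 * (mu0 - mu1)^2`` on bin indices, ties broken by the smallest
    threshold.
    """
    c = np.asarray(marginal, dtype=np.float64)
    n = c.sum()
    if (c > 0).sum() < 2:
        raise DegenerateHistogramError("1D histogram has a single occupied bin")
    idx = np.arange(len(c))
    w0 = c.cumsum()
    s0 = (c * idx).cumsum()
    w1 = n - w0
    s1 = s0[-1] - s0
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        obj = np.where(valid, w0 * w1 / n ** 2 * (s0 / w0 - s1 / w1) ** 2, -np.inf)
    t = int(np.argmax(obj))  # argmax takes the first (smallest) maximiser
    return t, float(obj[t])


def segment_block(block: VolumeStack | np.ndarray, prm_map: np.ndarray,
                  roi: np.ndarray | SegmentationMask | None = None,
                  bins: tuple[int, int] = (64, 64)) -> SegmentationMask:
    """Binary mask from the joint 2D-Otsu threshold, restricted to the ROI.

    Blocks whose PRM map has no support fall back to an empty mask with a
    warning (no peak means no detected object to segment).
    """
    data = block.data if isinstance(block, VolumeStack) else np.asarray(block)
    spacing = block.spacing if isinstance(block, VolumeStack) else (1.0, 1.0, 1.0)
    prm_map = np.asarray(prm_map)
    if roi is not None and isinstance(roi, SegmentationMask):
        roi = roi.data
    if prm_map.max() <= 0:
        warnings.warn("PRM map has no support; returning an empty mask")
        return SegmentationMask(np.zeros(data.shape, bool), spacing)
    h = joint_histogram(data, prm_map, bins, roi)
    try:
        thr = otsu2d_threshold(h)
    except DegenerateHistogramError:
        warnings.warn("degenerate joint histogram; returning an empty mask")
        return SegmentationMask(np.zeros(data.shape, bool), spacing)
    bi, bp = h.counts.shape
    mask = (_bin_indices(data, bi) > thr.t_intensity) \
        & (_bin_indices(prm_map, bp) > thr.t_prm)
    if roi is not None:
        mask &= np.asarray(roi, bool)
    return SegmentationMask(mask, spacing)


def montage(grid: BlockGrid, block_masks: dict[int, SegmentationMask | np.ndarray],
            spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
            ) -> SegmentationMask:
    """Reassemble per-block masks into the whole-volume mask.

    ``block_masks`` maps block index -> mask; every kept block must be
    present, dropped blocks contribute zeros, and edge padding is cropped so
    the result matches the original volume shape.  Objects crossing block
    borders merge back into single connected components.
    """
    out = np.zeros(grid.padded_shape, dtype=bool)
    for idx in grid.kept_indices():
        if int(idx) not in block_masks:
            raise ValueError(f"missing mask for kept block {int(idx)}")
    for idx, m in block_masks.items():
        data = m.data if isinstance(m, SegmentationMask) else np.asarray(m, bool)
        if data.shape != tuple(grid.block_shape):
            raise ValueError(
                f"block {idx}: mask shape {data.shape} != block shape "
                f"{tuple(grid.block_shape)}"
            )
        o = grid.origins[int(idx)]
        sl = tuple(slice(int(a), int(a) + b) for a, b in zip(o, grid.block_shape))
        out[sl] = data
    crop = tuple(slice(0, s) for s in grid.volume_shape)
    return SegmentationMask(out[crop], spacing)


def detection_roi(shape: tuple[int, int, int], boxes, tissue=None,
                  dilate: int = 4) -> np.ndarray:
    """ROI = union of detection boxes dilated by ``dilate`` voxels, within tissue.

    Restricting the histogram to the neighbourhood of detections keeps the
    background from dominating the joint histogram.
    """
    roi = np.zeros(shape, dtype=bool)
    for b in boxes:
        lo = [max(0, a - dilate) for a in b.zyx_min]
        hi = [min(s, a + dilate) for a, s in zip(b.zyx_max, shape)]
        roi[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    if tissue is not None:
        t = tissue.data if isinstance(tissue, SegmentationMask) else np.asarray(tissue, bool)
        roi &= t
    return roi
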