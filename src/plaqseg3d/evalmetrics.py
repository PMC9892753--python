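"""Segmentation evaluation: Dice score, sensitivity, and 95% Hausdorff
distance.

DSC = 2TP / (2TP + FP + FN) weighs interior voxels; SST = TP / (TP + FN)
measures how much ground truth was recovered; HD95 is the 95th percentile of
the pooled directed nearest-neighbour distances between the two foreground
voxel sets (spacing-scaled Euclidean metric), robust to a few boundary
outliers where the plain Hausdorff maximum is not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volio import SegmentationMask

__all__ = ["ConfusionCounts", "confusion", "dice", "sensitivity", "hd95",
           "evaluate"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def _as_bool(m) -> np.ndarray:
    return m.data if isinstance(m, SegmentationMask) else np.asarray(m, bool)


def confusion(pred, gt) -> ConfusionCounts:
    """Voxelwise confusion counts between two equal-shape binary masks."""
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dice(c: ConfusionCounts) -> float:
    """DSC = 2TP / (2TP + FP + FN); both-empty masks score 1 by convention."""
    denom = 2 * c.TP + c.FP + c.FN
    if denom == 0:
        warnings.warn("both masks empty; Dice defined as 1.0 by convention")
        return 1.0
    return 2.0 * c.TP / denom


def sensitivity(c: ConfusionCounts) -> float:
    """SST = TP / (TP + FN); undefined (error) for an empty ground truth."""
    denom = c.TP + c.FN
    if denom == 0:
        raise ValueError("sensitivity undefined: ground truth is empty")
    return c.TP / denom


def hd95(pred, gt, spacing=(1.0, 1.0, 1.0), percentile: float = 95.0,
         surface_only: bool = False) -> float:
    """95th percentile of pooled directed nearest-neighbour distances (in the
    spacing's units, conventionally micrometres).

    Distances are computed between the full foreground voxel coordinate sets
    of the two masks with an exact Euclidean distance transform; the two
    directed distance multisets are pooled and the percentile taken with
    linear interpolation.  Symmetric by construction; 0 for identical masks.
    ``surface_only`` restricts both sets to boundary voxels (a voxel with at
    least one 6-neighbour outside the mask), off by default.  Empty masks
    are an error (the distance is undefined).
    """
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    if surface_only:
        p = p & ~ndimage.binary_erosion(p)
        g = g & ~ndimage.binary_erosion(g)
    if not p.any() or not g.any():
        raise ValueError("HD undefined for an empty mask")
    sp = tuple(float(s) for s in spacing)
    # exact EDT of the complement gives d(x, S) for every voxel x
    d_to_g = ndimage.distance_transform_edt(~g, sampling=sp)
    d_to_p = ndimage.distance_transform_edt(~p, sampling=sp)
    pooled = np.concatenate([d_to_g[p], d_to_p[g]])
    return float(np.percentile(pooled, percentile, method="linear"))


def evaluate(pred, gt, spacing=(1.0, 1.0, 1.0)) -> dict:
    """The metric trio as a dict: dice, sst, hd95_um."""
    c = confusion(pred, gt)
    out = {"dice": dice(c)}
    out["sst"] = sensitivity(c) if (c.TP + c.FN) else float("nan")
    if _as_bool(pred).any() and _as_bool(gt).any():
        out["hd95_um"] = hd95(pred, gt, spacing)
    else:
        out["hd95_um"] = float("nan")
    return out
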