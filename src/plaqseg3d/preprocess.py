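"""Preprocessing: tissue masking, per-slice brightness calibration, SNR
enhancement, and partition of large stacks into fixed-size blocks.

Brightness varies with imaging depth (antibody penetration and light
absorption), so each slice is rescaled by the ratio of the mid-slice tissue
mean to its own tissue mean:

    I'(z) = I(z) / (I_mean(z) / I_mean(z_mid))

with the mean taken over tissue voxels only.  SNR is then improved with a 3D
Gaussian blur (sigma 2, chosen small to preserve detail).  Finally the stack
is partitioned into non-overlapping blocks (default 75 x 256 x 256 in z,y,x)
and blocks with under 1% tissue voxels are dropped from training and testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import ball

from .volio import SegmentationMask, VolumeStack

__all__ = [
    "CalibrationProfile",
    "BlockGrid",
    "NoTissueError",
    "compute_tissue_mask",
    "calibrate_brightness",
    "enhance_snr",
    "partition_blocks",
    "extract_block",
    "DEFAULT_BLOCK_SHAPE",
    "DEFAULT_MIN_TISSUE_FRACTION",
]

#: canonical (z, y, x) form of the 256 x 256 x 75 (y, x, z) processing block
DEFAULT_BLOCK_SHAPE = (75, 256, 256)
DEFAULT_MIN_TISSUE_FRACTION = 0.01


class NoTissueError(ValueError):
    """Raised when no tissue can be distinguished from background."""


@dataclass
class CalibrationProfile:
    """Per-slice tissue means and the gains applied to remove depth decay."""

    mean_intensity: np.ndarray   # m(z), tissue mean per slice (nan where no tissue)
    mid_index: np.ndarray        # z_mid per slice (reference slice of its section)
    gain: np.ndarray             # g(z) = m(z_mid) / m(z); slices are divided by 1/g

    def __post_init__(self) -> None:
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=np.float64)
        self.gain = np.asarray(self.gain, dtype=np.float64)


@dataclass
class BlockGrid:
    """Non-overlapping block partition covering the (padded) volume."""

    block_shape: tuple[int, int, int]          # (z, y, x)
    origins: np.ndarray                        # (n, 3) corner coordinates
    kept: np.ndarray                           # (n,) bool
    tissue_fraction: np.ndarray                # (n,) float
    volume_shape: tuple[int, int, int]
    padded_shape: tuple[int, int, int]

    @property
    def n_blocks(self) -> int:
        return len(self.origins)

    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.kept)


def compute_tissue_mask(v: VolumeStack, downsample: int = 4,
                        closing_radius: int = 2) -> SegmentationMask:
    """Segment tissue from the dark non-brain surround.

    A global threshold is estimated on a downsampled copy and applied at full
    resolution, followed by morphological closing, largest-component
    selection and hole filling.  Because stained volumes are typically
    trimodal (dark surround, moderate tissue, bright objects), the threshold
    is the lowest cut of a three-class multi-Otsu, falling back to plain Otsu
    for bimodal data.  Constant volumes (no separable modes) raise
    :class:`NoTissueError`.
    """
    data = np.asarray(v.data, dtype=np.float32)
    small = data[::downsample, ::downsample, ::downsample]
    if np.ptp(small) == 0:
        raise NoTissueError("no tissue found: volume is constant")
    try:
        t = threshold_multiotsu(small, classes=3)[0]
    except ValueError:  # fewer than 3 distinct grey levels
        t = threshold_otsu(small)
    fg = data > t
    if not fg.any():
        raise NoTissueError("no tissue found above the Otsu threshold")
    if closing_radius > 0:
        fg = ndimage.binary_closing(fg, structure=ball(closing_radius))
    lab = cc_label(fg, connectivity=3)
    if lab.max() > 1:
        sizes = np.bincount(lab.ravel())[1:]
        fg = lab == (int(np.argmax(sizes)) + 1)
    fg = ndimage.binary_fill_holes(fg)
    return SegmentationMask(fg, v.spacing)


def calibrate_brightness(
    v: VolumeStack,
    tissue: SegmentationMask,
    section_size: int | None = None,
) -> tuple[VolumeStack, CalibrationProfile]:
    """Remove the multiplicative per-slice depth profile.

    Each slice is divided by ``m(z) / m(z_mid)`` where ``m`` is its tissue
    mean and ``z_mid`` the middle slice of its section (``floor(n/2)`` within
    each contiguous ``section_size`` chunk; the whole stack is one section
    when ``section_size`` is None).  Slices without tissue keep gain 1 with a
    warning.  Non-tissue voxels are scaled by the same per-slice gain.
    """
    if v.data.shape != tissue.data.shape:
        raise ValueError("tissue mask shape must match volume shape")
    data = np.asarray(v.data, dtype=np.float64)
    tis = tissue.data
    nz = data.shape[0]
    sec = section_size or nz

    counts = tis.reshape(nz, -1).sum(axis=1)
    sums = np.where(tis, data, 0.0).reshape(nz, -1).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    gain = np.ones(nz, dtype=np.float64)
    mid = np.zeros(nz, dtype=np.int64)
    warned = False
    for start in range(0, nz, sec):
        stop = min(start + sec, nz)
        z_mid = start + (stop - start) // 2
        # if the nominal mid slice has no tissue, use the nearest slice that has
        valid = [z for z in range(start, stop) if counts[z] > 0 and m[z] > 0]
        if not valid:
            warned = True
            mid[start:stop] = z_mid
            continue
        if counts[z_mid] == 0 or not (m[z_mid] > 0):
            z_mid = min(valid, key=lambda z: abs(z - z_mid))
        ref = m[z_mid]
        for z in range(start, stop):
            mid[z] = z_mid
            if counts[z] > 0 and m[z] > 0:
                gain[z] = ref / m[z]
            else:
                warned = True
    if warned:
        warnings.warn("slices without tissue (or zero tissue mean) kept gain 1")

    out = (data * gain[:, None, None]).astype(np.float32)
    profile = CalibrationProfile(mean_intensity=m, mid_index=mid, gain=gain)
    return (
        VolumeStack(out, v.spacing, v.dtype_range, dict(v.meta)),
        profile,
    )


def enhance_snr(v: VolumeStack, sigma: float = 2.0) -> VolumeStack:
    """3D Gaussian blur (reflect boundaries) to raise SNR before detection."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    out = ndimage.gaussian_filter(
        np.asarray(v.data, dtype=np.float32), sigma=sigma, mode="reflect"
    )
    return VolumeStack(out, v.spacing, v.dtype_range, dict(v.meta))


def partition_blocks(
    v: VolumeStack,
    tissue: SegmentationMask,
    block_shape: tuple[int, int, int] = DEFAULT_BLOCK_SHAPE,
    min_tissue_frac: float = DEFAULT_MIN_TISSUE_FRACTION,
) -> BlockGrid:
    """Tile the volume into non-overlapping blocks from origin (0, 0, 0).

    Edge blocks are zero-padded to the full block shape (padding recorded via
    ``padded_shape`` so the montage can crop).  A block is kept iff its
    tissue-voxel fraction (over the full, padded block voxel count) is at
    least ``min_tissue_frac``.
    """
    if v.data.shape != tissue.data.shape:
        raise ValueError("tissue mask shape must match volume shape")
    bs = tuple(int(b) for b in block_shape)
    if any(b < 1 for b in bs):
        raise ValueError("block_shape must be positive")
    shape = v.data.shape
    n_along = [int(np.ceil(s / b)) for s, b in zip(shape, bs)]
    padded = tuple(n * b for n, b in zip(n_along, bs))

    origins, fracs = [], []
    block_voxels = int(np.prod(bs))
    for iz in range(n_along[0]):
        for iy in range(n_along[1]):
            for ix in range(n_along[2]):
                o = (iz * bs[0], iy * bs[1], ix * bs[2])
                sl = tuple(slice(a, min(a + b, s)) for a, b, s in zip(o, bs, shape))
                n_tissue = int(tissue.data[sl].sum())
                origins.append(o)
                fracs.append(n_tissue / block_voxels)
    fracs_arr = np.asarray(fracs, dtype=np.float64)
    return BlockGrid(
        block_shape=bs,
        origins=np.asarray(origins, dtype=np.int64),
        kept=fracs_arr >= min_tissue_frac,
        tissue_fraction=fracs_arr,
        volume_shape=shape,
        padded_shape=padded,
    )


def extract_block(data: np.ndarray, grid: BlockGrid, index: int) -> np.ndarray:
    """Cut block ``index`` out of a full-volume array, zero-padded at edges."""
    o = grid.origins[index]
    bs = grid.block_shape
    shape = data.shape
    sl = tuple(slice(int(a), min(int(a) + b, s)) for a, b, s in zip(o, bs, shape))
    chunk = data[sl]
    if chunk.shape == tuple(bs):
        return np.ascontiguousarray(chunk)
    out = np.zeros(bs, dtype=data.dtype)
    out[tuple(slice(0, c) for c in chunk.shape)] = chunk
    return out
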