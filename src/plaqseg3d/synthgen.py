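"""Synthetic volumes with plaque-like blobs, weak labels, and a toy atlas.

The generator emulates the statistical structure the pipeline assumes in real
immunostained light-sheet data: bright, roughly Gaussian blobs spanning three
size classes (small < 300, medium 300-1500, big > 1500 voxels), a
depth-dependent multiplicative brightness profile ``b(z)``, additive Gaussian
sensor noise, and an ellipsoidal "brain" of moderate background intensity
surrounded by near-zero non-tissue voxels.  A nearest-seed (Voronoi) partition
of the brain ellipsoid stands in for an anatomical atlas.

All randomness flows through one ``numpy.random.Generator`` seeded from the
scene config, so identical configs produce bit-identical scenes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import numpy as np

from .volio import BoundingBox3D, RegionLabelVolume, SegmentationMask, VolumeStack

__all__ = [
    "PlaqueSpec",
    "SceneConfig",
    "SyntheticScene",
    "PlacementError",
    "generate_scene",
    "generate_toy_atlas",
    "SIZE_CLASS_RADII",
]

#: half-max radius ranges (voxels) that keep rendered volumes inside each class
SIZE_CLASS_RADII = {
    "small": (2.0, 3.8),
    "medium": (4.3, 6.6),
    "big": (7.2, 9.0),
}

_CLASS_BOUNDS = {"small": (1, 299), "medium": (300, 1500), "big": (1501, 10**9)}


class PlacementError(RuntimeError):
    """Raised when a plaque cannot be placed without overlap."""


@dataclass(frozen=True)
class PlaqueSpec:
    """One rendered blob: Gaussian profile with half-max ellipsoid ``radii``.

    The blob is ``peak * exp(-0.5 * sum(((v - center) / sigma)**2))`` with
    ``sigma = radii / sqrt(2 ln 2)`` so that the half-max isosurface is the
    ellipsoid with semi-axes ``radii``; the ground-truth mask is exactly the
    lattice points inside that ellipsoid.
    """

    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    peak_intensity: float
    size_class: str

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if not (0.0 < self.peak_intensity <= 1.0):
            raise ValueError("peak_intensity must lie in (0, 1]")
        if self.size_class not in _CLASS_BOUNDS:
            raise ValueError(f"unknown size class {self.size_class!r}")

    def mask_voxel_count(self) -> int:
        """Exact number of lattice voxels inside the half-max ellipsoid."""
        return _count_ellipsoid(self.center, self.radii)


def _count_ellipsoid(center, radii) -> int:
    zz, yy, xx = _local_grid(center, radii)
    return int((zz + yy + xx <= 1.0 + 1e-12).sum())


def _local_grid(center, radii):
    """Squared normalised coordinates on the minimal lattice box around the blob."""
    axes = []
    for c, r in zip(center, radii):
        lo = math.floor(c - r)
        hi = math.ceil(c + r)
        axes.append((np.arange(lo, hi + 1) - c) / r)
    z, y, x = axes
    return (
        (z ** 2)[:, None, None],
        (y ** 2)[None, :, None],
        (x ** 2)[None, None, :],
    )


def _ellipsoid_support(center, radii, shape):
    """Boolean mask of lattice points inside the half-max ellipsoid."""
    if shape is None:
        zz, yy, xx = _local_grid(center, radii)
        return zz + yy + xx <= 1.0 + 1e-12
    out = np.zeros(shape, dtype=bool)
    lo = [max(0, math.floor(c - r)) for c, r in zip(center, radii)]
    hi = [min(s - 1, math.ceil(c + r)) for c, r, s in zip(center, radii, shape)]
    if any(h < l for l, h in zip(lo, hi)):
        return out
    axes = [((np.arange(l, h + 1) - c) / r) ** 2
            for l, h, c, r in zip(lo, hi, center, radii)]
    inside = axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :]
    out[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] = inside <= 1.0 + 1e-12
    return out


@dataclass
class SceneConfig:
    """Parameters of one synthetic scene.

    ``depth_decay`` is either ``None`` (flat profile), a length-Z array, or a
    callable ``b(z_indices) -> array``; it multiplies every voxel of slice z
    and must be positive.
    """

    shape: tuple[int, int, int] = (64, 128, 128)
    n_plaques: int = 30
    size_class_mix: tuple[float, float, float] = (0.4, 0.4, 0.2)  # small/medium/big
    depth_decay: np.ndarray | Callable[[np.ndarray], np.ndarray] | None = None
    noise_sd: float = 0.01
    background_level: float = 0.08
    peak_range: tuple[float, float] = (0.55, 0.95)
    brain_margin: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 1 for s in self.shape):
            raise ValueError("shape must be positive")
        if self.n_plaques < 0:
            raise ValueError("n_plaques must be >= 0")
        if abs(sum(self.size_class_mix) - 1.0) > 1e-9:
            raise ValueError("size_class_mix fractions must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def decay_profile(self) -> np.ndarray:
        z = np.arange(self.shape[0])
        if self.depth_decay is None:
            b = np.ones(self.shape[0])
        elif callable(self.depth_decay):
            b = np.asarray(self.depth_decay(z), dtype=np.float64)
        else:
            b = np.asarray(self.depth_decay, dtype=np.float64)
        if b.shape != (self.shape[0],):
            raise ValueError("depth profile must have one value per slice")
        if np.any(b <= 0):
            raise ValueError("depth profile b(z) must be positive")
        return b


@dataclass
class SyntheticScene:
    """Generated scene; unpacks as ``volume, mask, boxes`` for convenience."""

    volume: VolumeStack
    mask: SegmentationMask
    boxes: list[BoundingBox3D]
    brain_mask: SegmentationMask
    plaques: list[PlaqueSpec] = field(default_factory=list)
    config: SceneConfig | None = None

    def __iter__(self) -> Iterator:
        return iter((self.volume, self.mask, self.boxes))


def _brain_support(shape: tuple[int, int, int], margin: float) -> np.ndarray:
    """Ellipsoid filling the volume up to a fractional margin per axis."""
    semi = [max(1.0, (1.0 - margin) * s / 2.0) for s in shape]
    center = [(s - 1) / 2.0 for s in shape]
    axes = [((np.arange(s) - c) / a) ** 2 for s, c, a in zip(shape, center, semi)]
    return (axes[0][:, None, None] + axes[1][None, :, None]
            + axes[2][None, None, :]) <= 1.0


def brain_support(config: SceneConfig) -> SegmentationMask:
    """The in-brain (tissue) support that :func:`generate_scene` uses."""
    return SegmentationMask(_brain_support(config.shape, config.brain_margin))


def _sample_plaque(rng: np.random.Generator, cls: str, shape, brain, placed,
                   peak_range, index: int) -> PlaqueSpec:
    lo_r, hi_r = SIZE_CLASS_RADII[cls]
    lo_n, hi_n = _CLASS_BOUNDS[cls]
    for _ in range(300):
        base = rng.uniform(lo_r, hi_r)
        radii = tuple(float(np.clip(base * rng.uniform(0.85, 1.15), lo_r * 0.8, hi_r * 1.2))
                      for _ in range(3))
        margin = max(radii) + 1.0
        center = tuple(float(rng.uniform(margin, s - 1 - margin)) if s - 1 - margin > margin
                       else (s - 1) / 2.0 for s in shape)
        n_vox = _count_ellipsoid(center, radii)
        if not (lo_n <= n_vox <= hi_n):
            continue
        ci = tuple(int(round(c)) for c in center)
        if not brain[ci]:
            continue
        ok = True
        for p in placed:
            d = math.dist(center, p.center)
            if d < max(radii) + max(p.radii) + 1.0:
                ok = False
                break
        if not ok:
            continue
        peak = float(rng.uniform(*peak_range))
        return PlaqueSpec(center, radii, peak, cls)
    raise PlacementError(
        f"could not place plaque {index} (class {cls!r}) without overlap after 300 retries"
    )


_SIGMA_PER_RADIUS = 1.0 / math.sqrt(2.0 * math.log(2.0))


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render a synthetic scene with ground truth.

    Returns a :class:`SyntheticScene` whose volume is
    ``(background * brain + sum of blobs) * b(z) + N(0, noise_sd)`` clipped to
    ``[0, 1]``; the mask is the union of per-plaque half-max ellipsoids and
    each weak-label box is the tight half-open box of one plaque's mask.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    brain = _brain_support(shape, config.brain_margin)

    classes = ["small", "medium", "big"]
    counts = _mix_counts(config.n_plaques, config.size_class_mix)
    order = [c for c, n in zip(classes, counts) for _ in range(n)]
    rng.shuffle(order)

    clean = np.zeros(shape, dtype=np.float64)
    clean[brain] = config.background_level
    mask = np.zeros(shape, dtype=bool)
    plaques: list[PlaqueSpec] = []
    boxes: list[BoundingBox3D] = []

    for i, cls in enumerate(order):
        spec = _sample_plaque(rng, cls, shape, brain, plaques, config.peak_range, i)
        plaques.append(spec)
        support = _ellipsoid_support(spec.center, spec.radii, shape)
        mask |= support
        # render the Gaussian profile on a padded local box (3 sigma)
        sig = [r * _SIGMA_PER_RADIUS for r in spec.radii]
        lo = [max(0, math.floor(c - 3.5 * s)) for c, s in zip(spec.center, sig)]
        hi = [min(sz - 1, math.ceil(c + 3.5 * s)) for c, s, sz in zip(spec.center, sig, shape)]
        axes = [((np.arange(l, h + 1) - c) / s) ** 2
                for l, h, c, s in zip(lo, hi, spec.center, sig)]
        blob = spec.peak_intensity * np.exp(
            -0.5 * (axes[0][:, None, None] + axes[1][None, :, None] + axes[2][None, None, :])
        )
        clean[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1] += blob
        zz, yy, xx = np.nonzero(support)
        boxes.append(BoundingBox3D(
            (int(zz.min()), int(yy.min()), int(xx.min())),
            (int(zz.max()) + 1, int(yy.max()) + 1, int(xx.max()) + 1),
        ))

    b = config.decay_profile()
    vol = clean * b[:, None, None]
    if config.noise_sd > 0:
        vol = vol + rng.normal(0.0, config.noise_sd, size=shape)
    vol = np.clip(vol, 0.0, 1.0).astype(np.float32)

    meta = {"seed": config.seed, "generator": "plaqseg3d.synthgen"}
    return SyntheticScene(
        volume=VolumeStack(vol, (1.0, 1.0, 1.0), (0.0, 1.0), meta),
        mask=SegmentationMask(mask),
        boxes=boxes,
        brain_mask=SegmentationMask(brain),
        plaques=plaques,
        config=config,
    )


def _mix_counts(n: int, mix: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n plaques over the class mix."""
    raw = [n * f for f in mix]
    counts = [int(math.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # most negative first
    for i in range(rem):
        counts[order[i]] += 1
    return counts


def generate_toy_atlas(shape: tuple[int, int, int], n_regions: int,
                       seed: int = 0, margin: float = 0.04) -> RegionLabelVolume:
    """Voronoi partition of an ellipsoidal brain into ``n_regions`` labels.

    Every in-brain voxel gets the label of its nearest seed point (labels
    1..n_regions); voxels outside the ellipsoid are 0.  Cells are convex
    intersected with a convex ellipsoid, hence connected.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    brain = _brain_support(tuple(shape), margin)
    n_inside = int(brain.sum())
    if n_regions > n_inside:
        raise ValueError(f"n_regions={n_regions} exceeds in-brain voxel count {n_inside}")
    rng = np.random.default_rng(seed)
    coords = np.argwhere(brain)
    seeds = coords[rng.choice(n_inside, size=n_regions, replace=False)]
    # nearest seed per voxel, computed blockwise to bound memory
    labels = np.zeros(shape, dtype=np.uint16)
    flat = coords.astype(np.float64)
    best = np.full(len(flat), -1, dtype=np.int64)
    best_d = np.full(len(flat), np.inf)
    for i, s in enumerate(seeds.astype(np.float64)):
        d = np.sum((flat - s) ** 2, axis=1)
        upd = d < best_d
        best_d[upd] = d[upd]
        best[upd] = i
    labels[tuple(coords.T)] = best.astype(np.uint16) + 1
    names = {i + 1: f"region_{i + 1:02d}" for i in range(n_regions)}
    return RegionLabelVolume(labels.astype(np.int32), names)
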