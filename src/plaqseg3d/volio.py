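"""Core volumetric data model and I/O shared by every pipeline stage.

Conventions used throughout the package:

* axis order is ``(z, y, x)``, 0-based;
* bounding boxes are half-open integer voxel boxes ``[zyx_min, zyx_max)``;
* intensities are normalised to float32 in ``[0, 1]`` on ingestion, with the
  storage dtype range recorded so exports can restore the original scale.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import nibabel as nib
import numpy as np
import tifffile

__all__ = [
    "VolumeStack",
    "BoundingBox3D",
    "SegmentationMask",
    "RegionLabelVolume",
    "VolumeIOError",
    "NonVolumeError",
    "UnknownFormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_labels",
    "write_labels",
    "read_boxes",
    "write_boxes",
    "iou3d",
]


class VolumeIOError(IOError):
    """Base error for volume reading/writing failures."""


class NonVolumeError(VolumeIOError):
    """The file parsed, but its payload is not a 3D volume."""


class UnknownFormatError(VolumeIOError):
    """Requested or inferred format is not supported."""


_INT_RANGES = {
    np.dtype(np.uint8): (0.0, 255.0),
    np.dtype(np.uint16): (0.0, 65535.0),
    np.dtype(np.int16): (-32768.0, 32767.0),
    np.dtype(np.uint32): (0.0, 4294967295.0),
}


@dataclass
class VolumeStack:
    """A 3D intensity volume with physical voxel spacing.

    Parameters
    ----------
    data
        3D scalar array indexed ``(z, y, x)``.
    spacing
        Voxel size ``(dz, dy, dx)`` in micrometres.
    dtype_range
        ``(min, max)`` of the on-disk storage type; used to undo the
        ``[0, 1]`` normalisation on export.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    dtype_range: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise NonVolumeError(
                f"expected a 3D (z, y, x) array, got ndim={self.data.ndim}"
            )
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        sp = tuple(float(s) for s in self.spacing)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be three positive floats, got {self.spacing}")
        self.spacing = sp
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def normalized(self) -> "VolumeStack":
        """Return a float32 copy with intensities scaled to ``[0, 1]``."""
        d = self.data
        if np.issubdtype(d.dtype, np.floating) and self.dtype_range is None:
            return VolumeStack(d.astype(np.float32, copy=True), self.spacing,
                               (0.0, 1.0), dict(self.meta))
        lo, hi = self.dtype_range or _INT_RANGES.get(d.dtype, (float(d.min()), float(d.max())))
        if hi <= lo:
            hi = lo + 1.0
        out = (d.astype(np.float32) - lo) / (hi - lo)
        return VolumeStack(out, self.spacing, (lo, hi), dict(self.meta))


@dataclass(frozen=True)
class BoundingBox3D:
    """Axis-aligned half-open voxel box ``[zyx_min, zyx_max)``."""

    zyx_min: tuple[int, int, int]
    zyx_max: tuple[int, int, int]
    score: float | None = None

    def __post_init__(self) -> None:
        mn = tuple(int(v) for v in self.zyx_min)
        mx = tuple(int(v) for v in self.zyx_max)
        object.__setattr__(self, "zyx_min", mn)
        object.__setattr__(self, "zyx_max", mx)
        if any(b <= a for a, b in zip(mn, mx)):
            raise ValueError(f"degenerate box: min={mn} max={mx}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @property
    def volume(self) -> int:
        return int(np.prod([b - a for a, b in zip(self.zyx_min, self.zyx_max)]))

    @property
    def center(self) -> tuple[float, float, float]:
        return tuple((a + b) / 2.0 for a, b in zip(self.zyx_min, self.zyx_max))  # type: ignore[return-value]

    @property
    def size(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.zyx_min, self.zyx_max))  # type: ignore[return-value]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.zyx_min, self.zyx_max))  # type: ignore[return-value]


@dataclass
class SegmentationMask:
    """Binary 3D mask sharing grid and spacing with its source volume."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise NonVolumeError(f"mask must be 3D, got ndim={d.ndim}")
        if d.dtype != bool:
            u = np.unique(d)
            if not np.all(np.isin(u, (0, 1))):
                raise ValueError("mask values must be in {0, 1}")
            d = d.astype(bool)
        self.data = d
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class RegionLabelVolume:
    """Integer label volume; 0 marks voxels outside every region."""

    data: np.ndarray
    label_names: Mapping[int, str]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise NonVolumeError(f"label volume must be 3D, got ndim={d.ndim}")
        if not np.issubdtype(d.dtype, np.integer):
            raise ValueError("labels must be integers")
        if d.min() < 0:
            raise ValueError("labels must be non-negative")
        self.data = d
        present = set(np.unique(d)) - {0}
        missing = present - set(int(k) for k in self.label_names)
        if missing:
            raise ValueError(f"labels without names: {sorted(missing)}")
        self.label_names = {int(k): str(v) for k, v in self.label_names.items()}
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def labels(self) -> list[int]:
        return sorted(set(np.unique(self.data)) - {0})


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = ("tiff", "nifti", "hdf5")
_SUFFIX_FORMAT = {
    ".tif": "tiff", ".tiff": "tiff",
    ".nii": "nifti", ".gz": "nifti",
    ".h5": "hdf5", ".hdf5": "hdf5",
}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise UnknownFormatError(f"unknown format {fmt!r}; supported: {_FORMATS}")
        return fmt
    guess = _SUFFIX_FORMAT.get(path.suffix.lower())
    if guess is None:
        raise UnknownFormatError(f"cannot infer format from suffix {path.suffix!r}")
    return guess


def read_volume(path: str | Path, format: str | None = None) -> VolumeStack:
    """Read a 3D volume from multi-page TIFF, NIfTI-1 or HDF5.

    Spacing ``(dz, dy, dx)`` is taken from the file header where available;
    otherwise it defaults to ``(1, 1, 1)`` with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    fmt = _infer_format(path, format)
    if fmt == "tiff":
        data = tifffile.imread(path)
        if data.ndim != 3:
            raise NonVolumeError(f"non-3D payload in {path}: ndim={data.ndim}")
        warnings.warn(f"no spacing metadata read from TIFF {path.name}; assuming 1 um isotropic")
        return VolumeStack(data, (1.0, 1.0, 1.0), _int_range(data))
    if fmt == "nifti":
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if data.ndim != 3:
            raise NonVolumeError(f"non-3D payload in {path}: ndim={data.ndim}")
        # NIfTI stores (x, y, z); transpose to canonical (z, y, x)
        zooms = img.header.get_zooms()[:3]
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        return VolumeStack(np.ascontiguousarray(data.T), spacing, _int_range(data))
    # hdf5
    with h5py.File(path, "r") as f:
        if "volume" not in f:
            raise NonVolumeError(f"HDF5 file {path} has no 'volume' dataset")
        ds = f["volume"]
        data = ds[()]
        if data.ndim != 3:
            raise NonVolumeError(f"non-3D payload in {path}: ndim={data.ndim}")
        if "spacing_um" in ds.attrs:
            spacing = tuple(float(s) for s in ds.attrs["spacing_um"])
        else:
            warnings.warn(f"no spacing_um attribute in {path.name}; assuming 1 um isotropic")
            spacing = (1.0, 1.0, 1.0)
    return VolumeStack(data, spacing, _int_range(data))


def _int_range(data: np.ndarray) -> tuple[float, float] | None:
    return _INT_RANGES.get(data.dtype)


def write_volume(v: VolumeStack, path: str | Path, format: str | None = None) -> Path:
    """Write a volume; format inferred from the suffix unless given."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fmt = _infer_format(path, format)
    if fmt == "tiff":
        tifffile.imwrite(path, v.data, photometric="minisblack")
    elif fmt == "nifti":
        affine = np.diag([v.spacing[2], v.spacing[1], v.spacing[0], 1.0])
        img = nib.Nifti1Image(np.ascontiguousarray(v.data.T), affine)
        img.header.set_zooms((v.spacing[2], v.spacing[1], v.spacing[0]))
        nib.save(img, str(path))
    else:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset("volume", data=v.data)
            ds.attrs["spacing_um"] = np.asarray(v.spacing, dtype=np.float64)
    return path


def write_mask(m: SegmentationMask, path: str | Path) -> Path:
    return write_volume(
        VolumeStack(m.data.astype(np.uint8), m.spacing, (0.0, 255.0)), path
    )


def read_mask(path: str | Path) -> SegmentationMask:
    v = read_volume(path)
    return SegmentationMask(v.data > 0, v.spacing)


def write_labels(r: RegionLabelVolume, path: str | Path) -> Path:
    p = write_volume(VolumeStack(r.data.astype(np.uint16), r.spacing), path)
    names_path = Path(str(p) + ".labels.json")
    names_path.write_text(json.dumps({str(k): v for k, v in r.label_names.items()}, indent=2))
    return p


def read_labels(path: str | Path) -> RegionLabelVolume:
    v = read_volume(path)
    names_path = Path(str(path) + ".labels.json")
    if names_path.exists():
        names = {int(k): v2 for k, v2 in json.loads(names_path.read_text()).items()}
    else:
        names = {int(k): f"region_{int(k)}" for k in np.unique(v.data) if k != 0}
    return RegionLabelVolume(v.data.astype(np.int32), names, v.spacing)


def write_boxes(boxes: Sequence[BoundingBox3D], path: str | Path) -> Path:
    """Serialise boxes to the package's JSON dialect."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = []
    for i, b in enumerate(boxes):
        rec = {"id": i, "zyx_min": list(b.zyx_min), "zyx_max": list(b.zyx_max)}
        if b.score is not None:
            rec["score"] = float(b.score)
        records.append(rec)
    path.write_text(json.dumps(records, indent=2))
    return path


def read_boxes(path: str | Path) -> list[BoundingBox3D]:
    records = json.loads(Path(path).read_text())
    return [
        BoundingBox3D(tuple(r["zyx_min"]), tuple(r["zyx_max"]), r.get("score"))
        for r in records
    ]


# ---------------------------------------------------------------------------
# Box geometry
# ---------------------------------------------------------------------------

def iou3d(a: BoundingBox3D, b: BoundingBox3D) -> float:
    """Intersection-over-union of two half-open voxel boxes, in [0, 1]."""
    inter = 1
    for lo_a, hi_a, lo_b, hi_b in zip(a.zyx_min, a.zyx_max, b.zyx_min, b.zyx_max):
        lo, hi = max(lo_a, lo_b), min(hi_a, hi_b)
        if hi <= lo:
            return 0.0
        inter *= hi - lo
    union = a.volume + b.volume - inter
    return inter / union


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between ``(n, 6)`` and ``(m, 6)`` box arrays.

    Boxes are rows ``(z0, y0, x0, z1, y1, x1)`` in half-open voxel coordinates.
    """
    a = np.asarray(boxes_a, dtype=np.float64).reshape(-1, 6)
    b = np.asarray(boxes_b, dtype=np.float64).reshape(-1, 6)
    lo = np.maximum(a[:, None, :3], b[None, :, :3])
    hi = np.minimum(a[:, None, 3:], b[None, :, 3:])
    inter = np.prod(np.clip(hi - lo, 0, None), axis=-1)
    va = np.prod(a[:, 3:] - a[:, :3], axis=-1)
    vb = np.prod(b[:, 3:] - b[:, :3], axis=-1)
    union = va[:, None] + vb[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def boxes_to_array(boxes: Sequence[BoundingBox3D]) -> np.ndarray:
    if not boxes:
        return np.zeros((0, 6), dtype=np.float64)
    return np.asarray([[*b.zyx_min, *b.zyx_max] for b in boxes], dtype=np.float64)
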