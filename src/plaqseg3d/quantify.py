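"""Region-wise quantification of plaque masks.

Connected components of the whole-volume mask (26-connectivity by default)
become plaque records, classified by voxel count on a 4 um isotropic
analysis grid into small (< 300), medium (300-1500) and big (> 1500)
plaques.  Each plaque is assigned to the atlas region holding the majority
of its voxels, and per-region totals, counts, volume ratios, count densities
(per mm^3) and mean volumes are tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volio import RegionLabelVolume, SegmentationMask

__all__ = [
    "PlaqueRecord", "SIZE_THRESHOLDS", "ANALYSIS_SPACING_UM",
    "label_components", "classify_size", "resample_to_analysis_grid",
    "region_stats", "plaque_table",
]

#: size-class boundaries in voxels on the 4 um grid: small < 300,
#: medium 300-1500 (inclusive), big > 1500
SIZE_THRESHOLDS = (300, 1500)
ANALYSIS_SPACING_UM = 4.0


@dataclass
class PlaqueRecord:
    id: int
    voxel_count: int
    volume_um3: float
    centroid: tuple[float, float, float]
    size_class: str
    region_label: int = -1          # -1: unset; 0: outside every region
    voxel_indices: np.ndarray | None = None

    def __post_init__(self):
        if self.voxel_count < 1:
            raise ValueError("a plaque must contain at least one voxel")


def classify_size(voxel_count: int) -> str:
    """Size class from voxel count on the 4 um analysis grid."""
    if voxel_count < 1:
        raise ValueError("voxel_count must be >= 1")
    lo, hi = SIZE_THRESHOLDS
    if voxel_count < lo:
        return "small"
    if voxel_count <= hi:
        return "medium"
    return "big"


def label_components(mask: SegmentationMask | np.ndarray, connectivity: int = 26
                     ) -> list[PlaqueRecord]:
    """Maximal connected components as plaque records (region unset).

    Component ids are ordered by the lexicographic position of each
    component's first voxel, so the numbering is a pure function of the mask.
    """
    data = mask.data if isinstance(mask, SegmentationMask) else np.asarray(mask, bool)
    spacing = mask.spacing if isinstance(mask, SegmentationMask) else (1.0,) * 3
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    lab, n = ndimage.label(data, structure=structure)
    if n == 0:
        return []
    voxel_vol = float(np.prod(spacing))
    flat = lab.ravel()
    order = np.argsort(flat, kind="stable")
    counts = np.bincount(flat)
    # first occurrence (lexicographic) of each label in the flat order
    starts = np.cumsum(np.concatenate([[0], counts[:-1]]))
    first_pos = order[starts][1:]                    # first flat index, labels 1..n
    rank = np.argsort(np.argsort(first_pos, kind="stable"), kind="stable")
    com = ndimage.center_of_mass(data, lab, index=np.arange(1, n + 1))
    per_label_vox = np.split(order, starts[1:])[1:]  # voxel indices per label 1..n
    records = [
        PlaqueRecord(
            id=int(rank[k]),
            voxel_count=int(counts[k + 1]),
            volume_um3=float(counts[k + 1]) * voxel_vol,
            centroid=tuple(float(c) for c in com[k]),
            size_class=classify_size(int(counts[k + 1])),
            voxel_indices=per_label_vox[k],
        )
        for k in range(n)
    ]
    records.sort(key=lambda r: r.id)
    return records


def resample_to_analysis_grid(mask: SegmentationMask,
                              target_um: float = ANALYSIS_SPACING_UM
                              ) -> SegmentationMask:
    """Nearest-neighbour resampling of a mask to an isotropic grid.

    Output voxel ``i`` samples the source voxel containing the physical
    centre ``(i + 0.5) * target``; identity when the mask is already on the
    target grid.
    """
    sp = mask.spacing
    if all(abs(s - target_um) < 1e-12 for s in sp):
        return mask
    shape = mask.shape
    out_shape = tuple(int(np.ceil(s * d / target_um)) for s, d in zip(shape, sp))
    idx = [np.minimum((np.floor((np.arange(o) + 0.5) * target_um / d)).astype(np.int64),
                      s - 1)
           for o, d, s in zip(out_shape, sp, shape)]
    data = mask.data[np.ix_(*idx)]
    return SegmentationMask(data, (target_um,) * 3)


def _assign_regions(plaques: list[PlaqueRecord], atlas: RegionLabelVolume) -> None:
    flat_atlas = atlas.data.ravel()
    for p in plaques:
        if p.voxel_indices is None:
            raise ValueError("plaque records need voxel indices for assignment")
        labs = flat_atlas[p.voxel_indices]
        counts = np.bincount(labs)
        best = int(counts.max())
        p.region_label = int(np.flatnonzero(counts == best)[0])  # tie: smaller label


def region_stats(plaques: list[PlaqueRecord], atlas: RegionLabelVolume,
                 voxel_volume_um3: float | None = None,
                 split_volumes_pro_rata: bool = False,
                 exclude_labels: Sequence[int] = ()) -> pd.DataFrame:
    """Per-region plaque statistics.

    Each plaque is counted once, in the region holding the majority of its
    voxels (ties go to the smaller label; label 0 collects plaques outside
    every region and is reported as ``unassigned``).  With
    ``split_volumes_pro_rata`` the *volumes* (not the counts) are instead
    distributed across regions in proportion to each plaque's voxels there.
    ``exclude_labels`` drops regions (e.g. fibre tracts) from the table.
    Returns one row per atlas region (regions without plaques included with
    zeros) with columns label, name, region_volume_um3, total_volume_um3,
    plaque_count, volume_ratio, count_density_per_mm3, mean_volume_um3.
    """
    if voxel_volume_um3 is None:
        voxel_volume_um3 = float(np.prod(atlas.spacing))
    for p in plaques:
        if p.region_label < 0:
            _assign_regions(plaques, atlas)
            break
    excluded = {int(e) for e in exclude_labels}
    labels = [lab for lab in atlas.labels if lab not in excluded]
    region_vox = np.bincount(atlas.data.ravel(), minlength=max(labels, default=0) + 1)
    flat_atlas = atlas.data.ravel()
    pro_rata_vox: dict[int, float] = {}
    if split_volumes_pro_rata:
        for p in plaques:
            counts = np.bincount(flat_atlas[p.voxel_indices])
            for lab in np.flatnonzero(counts):
                pro_rata_vox[int(lab)] = pro_rata_vox.get(int(lab), 0.0) \
                    + float(counts[lab])
    rows = []
    for lab in [0] + labels:
        in_region = [p for p in plaques if p.region_label == lab]
        n = len(in_region)
        if split_volumes_pro_rata:
            vox = pro_rata_vox.get(lab, 0.0)
        else:
            vox = sum(p.voxel_count for p in in_region)
        total_um3 = vox * voxel_volume_um3
        rvol_um3 = float(region_vox[lab]) * voxel_volume_um3 if lab < len(region_vox) else 0.0
        rvol_mm3 = rvol_um3 * 1e-9
        rows.append({
            "label": lab,
            "name": "unassigned" if lab == 0 else atlas.label_names.get(lab, str(lab)),
            "region_volume_um3": rvol_um3,
            "total_volume_um3": total_um3,
            "plaque_count": n,
            "volume_ratio": total_um3 / rvol_um3 if rvol_um3 > 0 else 0.0,
            "count_density_per_mm3": n / rvol_mm3 if rvol_mm3 > 0 else 0.0,
            "mean_volume_um3": total_um3 / n if n else 0.0,
        })
    df = pd.DataFrame(rows).set_index("label")
    return df


def plaque_table(plaques: list[PlaqueRecord]) -> pd.DataFrame:
    """Per-plaque records as a DataFrame (one row per component)."""
    return pd.DataFrame([
        {
            "id": p.id,
            "voxel_count": p.voxel_count,
            "volume_um3": p.volume_um3,
            "centroid_z": p.centroid[0],
            "centroid_y": p.centroid[1],
            "centroid_x": p.centroid[2],
            "size_class": p.size_class,
            "region_label": p.region_label,
        }
        for p in plaques
    ])
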