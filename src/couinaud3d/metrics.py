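"""Quantitative segmentation metrics: DSC, MSD, HD and RV.

All four are computed per Couinaud segment and averaged (unweighted) over
the eight segments:

* DSC (%): voxel overlap, ``2|X n Y| / (|X| + |Y|) * 100``;
* MSD (mm): average symmetric surface distance,
  ``(sum_x min_y d(x,y) + sum_y min_x d(x,y)) / (N_X + N_Y)``;
* HD (mm): symmetric Hausdorff distance, the max of the two directed
  max-min surface distances;
* RV: predicted-to-reference volume ratio ``V_X / V_Y``.

Surfaces are voxel-center point sets in physical mm (voxels of a region
with at least one 6-connected background neighbor), so anisotropic
spacing is honored.  Nearest-neighbor distances use a KD-tree but are
contracted — and tested — to equal the brute-force all-pairs computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .grid import LabelMap, VolumeGrid

__all__ = [
    "EmptySurfaceError",
    "SurfaceSet",
    "SegMetrics",
    "extract_surface",
    "dsc",
    "msd",
    "hd",
    "rv",
    "evaluate_segmentation",
]

log = logging.getLogger(__name__)

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


class EmptySurfaceError(ValueError):
    """Surface-distance metric requested on an empty surface."""


@dataclass
class SurfaceSet:
    """Boundary voxel centers (mm) of a binary region."""

    points_mm: np.ndarray  # (N, 3)

    @property
    def count(self) -> int:
        return len(self.points_mm)


def _as_binary(region: VolumeGrid) -> np.ndarray:
    return np.asarray(region.data) > 0


def extract_surface(region: VolumeGrid) -> SurfaceSet:
    """Voxels of the region with a 6-connected background neighbor (mm).

    The grid edge counts as background, so a region touching the volume
    boundary is bounded by surface voxels there too.  An empty region
    yields an empty surface; consumers decide how to treat it.
    """
    mask = _as_binary(region)
    if not mask.any():
        return SurfaceSet(np.empty((0, 3)))
    interior = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    surf = mask & ~interior
    return SurfaceSet(region.world_coords(np.argwhere(surf)))


def dsc(x: VolumeGrid, y: VolumeGrid) -> float:
    """Dice similarity coefficient in percent; 100 for two empty regions."""
    mx, my = _as_binary(x), _as_binary(y)
    denom = int(mx.sum()) + int(my.sum())
    if denom == 0:
        log.debug("DSC of two empty regions defined as 100%%")
        return 100.0
    return 200.0 * int((mx & my).sum()) / denom


def _nearest_sums(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """(sum, max) of nearest-neighbor distances from each point of a to b."""
    d, _ = cKDTree(b).query(a)
    return float(d.sum()), float(d.max())


def msd(x: VolumeGrid, y: VolumeGrid) -> float:
    """Mean (average symmetric) surface distance in mm."""
    sx, sy = extract_surface(x), extract_surface(y)
    if sx.count == 0 or sy.count == 0:
        raise EmptySurfaceError("MSD undefined for an empty surface")
    sum_xy, _ = _nearest_sums(sx.points_mm, sy.points_mm)
    sum_yx, _ = _nearest_sums(sy.points_mm, sx.points_mm)
    return (sum_xy + sum_yx) / (sx.count + sy.count)


def hd(x: VolumeGrid, y: VolumeGrid) -> float:
    """Symmetric Hausdorff distance in mm over surface point sets."""
    sx, sy = extract_surface(x), extract_surface(y)
    if sx.count == 0 or sy.count == 0:
        raise EmptySurfaceError("HD undefined for an empty surface")
    _, max_xy = _nearest_sums(sx.points_mm, sy.points_mm)
    _, max_yx = _nearest_sums(sy.points_mm, sx.points_mm)
    return max(max_xy, max_yx)


def rv(x: VolumeGrid, y: VolumeGrid) -> float:
    """Volume ratio V_X / V_Y (volumes in mm^3)."""
    vy = int(_as_binary(y).sum()) * y.voxel_volume_mm3
    if vy == 0:
        raise EmptySurfaceError("RV undefined for an empty reference volume")
    vx = int(_as_binary(x).sum()) * x.voxel_volume_mm3
    return vx / vy


@dataclass
class SegMetrics:
    """Per-segment and averaged metrics between a prediction and a reference.

    ``per_label`` maps labels 1-8 to dicts with keys ``DSC_pct``,
    ``MSD_mm``, ``HD_mm``, ``RV`` (NaN where a metric is undefined);
    ``missing`` lists labels absent from the reference, excluded from the
    averages.
    """

    per_label: dict[int, dict[str, float]]
    averages: dict[str, float]
    missing: list[int] = field(default_factory=list)

    def to_dataframe(self, case: str = "") -> pd.DataFrame:
        rows = []
        for label in sorted(self.per_label):
            rows.append({"case": case, "label": f"S{label}", **self.per_label[label]})
        rows.append({"case": case, "label": "AVG", **self.averages})
        return pd.DataFrame(rows)


def evaluate_segmentation(pred: LabelMap, ref: LabelMap) -> SegMetrics:
    """All four metrics for each Couinaud label plus unweighted averages.

    A label absent from the reference is flagged missing and excluded from
    the averages; a label present in the reference but absent from the
    prediction contributes DSC 0 and RV 0, with MSD/HD undefined (NaN,
    excluded from their averages).
    """
    if pred.shape != ref.shape:
        raise ValueError("prediction and reference must share a grid")
    per_label: dict[int, dict[str, float]] = {}
    missing: list[int] = []
    for label in range(1, 9):
        px = VolumeGrid(np.asarray(pred.data) == label, pred.spacing, pred.origin)
        ry = VolumeGrid(np.asarray(ref.data) == label, ref.spacing, ref.origin)
        if not np.asarray(ry.data).any():
            missing.append(label)
            log.info("label S%d absent from reference; excluded from averages", label)
            per_label[label] = {
                "DSC_pct": np.nan, "MSD_mm": np.nan, "HD_mm": np.nan, "RV": np.nan,
            }
            continue
        entry = {"DSC_pct": dsc(px, ry), "RV": rv(px, ry)}
        try:
            entry["MSD_mm"] = msd(px, ry)
            entry["HD_mm"] = hd(px, ry)
        except EmptySurfaceError:
            entry["MSD_mm"] = np.nan
            entry["HD_mm"] = np.nan
        per_label[label] = entry
    present = [l for l in range(1, 9) if l not in missing]
    averages = {}
    for key in ("DSC_pct", "MSD_mm", "HD_mm", "RV"):
        vals = [per_label[l][key] for l in present]
        averages[key] = float(np.nanmean(vals)) if vals else np.nan
    return SegMetrics(per_label=per_label, averages=averages, missing=missing)
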