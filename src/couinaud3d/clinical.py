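"""Clinical-style evaluation of a Couinaud segmentation.

Three instruments, mirroring how automated liver-segment maps are judged in
practice:

* a qualitative rubric — each of the five separating planes is checked for
  how far it shifted off center (mm for the three vertical hepatic-vein
  planes, slices for the two horizontal portal planes), irregular
  mislabeled blobs are flagged as inter-segment faults, and the case is
  classified good / moderate / poor;
* an indirect evaluation — focal lesions are filtered (> 5 mm, at most the
  five largest per liver) and assigned to segments purely from the
  automated label map, then compared with their true segment sets;
* a linearly weighted kappa coefficient for ordinal inter-rater agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import HORIZONTAL_ROLES, PLANE_ROLES, Plane, fit_plane, signed_distance
from .grid import LabelMap

__all__ = [
    "Grade",
    "Lesion",
    "PlaneShift",
    "QualityReport",
    "UnlocalizableLesion",
    "PLANE_LABEL_GROUPS",
    "boundary_voxel_indices",
    "measure_plane_shift",
    "grade_shift",
    "detect_fault",
    "classify_quality",
    "quality_report",
    "filter_lesions",
    "localize_lesion",
    "weighted_kappa",
]


class Grade(str, Enum):
    NONE = "none"
    SLIGHT = "slight"
    MODERATE = "moderate"
    SEVERE = "severe"


# label groups on either side of each separating plane
PLANE_LABEL_GROUPS: dict[str, tuple[frozenset, frozenset]] = {
    "MID": (frozenset({2, 3, 4}), frozenset({5, 6, 7, 8})),
    "RHV": (frozenset({5, 8}), frozenset({6, 7})),
    "LHV_LLF": (frozenset({2, 3}), frozenset({4})),
    "RPV_H": (frozenset({7, 8}), frozenset({5, 6})),
    "LPV_H": (frozenset({2}), frozenset({3})),
}

# vertical planes graded in mm, horizontal in slices
_VERTICAL_THRESHOLDS = (5.0, 10.0)
_HORIZONTAL_THRESHOLDS = (2.0, 5.0)

_SIX_NEIGHBORS = [
    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1),
]


@dataclass
class Lesion:
    """A focal liver lesion: sphere of ``diameter_mm`` centered at ``center_mm``.

    ``true_segments`` is the set of Couinaud labels its voxels overlap in
    the reference label map; ``assigned_segments`` is filled in by
    :func:`localize_lesion` from an automated map.
    """

    id: int
    center_mm: np.ndarray
    diameter_mm: float
    mask: np.ndarray  # boolean, on the label map's grid
    true_segments: frozenset = frozenset()
    assigned_segments: frozenset | None = None
    hyper: bool = False

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        if self.diameter_mm <= 0:
            raise ValueError("lesion diameter must be positive")

    def to_dict(self) -> dict:
        d = {
            "id": int(self.id),
            "center_mm": self.center_mm.tolist(),
            "diameter_mm": float(self.diameter_mm),
            "true_segments": sorted(int(s) for s in self.true_segments),
            "hyper": bool(self.hyper),
        }
        if self.assigned_segments is not None:
            d["assigned_segments"] = sorted(int(s) for s in self.assigned_segments)
        return d


@dataclass
class PlaneShift:
    plane_role: str
    magnitude: float  # mm (vertical roles) or slices (horizontal roles)
    grade: Grade


@dataclass
class QualityReport:
    shifts: list[PlaneShift]
    fault: bool
    overall: str  # good | moderate | poor

    def to_dict(self) -> dict:
        return {
            "schema": "couinaud3d/v1",
            "shifts": [
                {"plane": s.plane_role, "magnitude": s.magnitude, "grade": s.grade.value}
                for s in self.shifts
            ],
            "fault": bool(self.fault),
            "overall": self.overall,
        }


class UnlocalizableLesion(Exception):
    """Lesion lies entirely outside the predicted liver; counted as a failure."""


def boundary_voxel_indices(
    labels: LabelMap, group_a: Iterable[int], group_b: Iterable[int]
) -> np.ndarray:
    """Indices of voxels in ``group_a`` with a 6-connected neighbor in ``group_b``."""
    arr = np.asarray(labels.data)
    in_a = np.isin(arr, list(group_a))
    in_b = np.isin(arr, list(group_b))
    touch = np.zeros_like(in_a)
    for dx, dy, dz in _SIX_NEIGHBORS:
        shifted = np.zeros_like(in_b)
        src = tuple(
            slice(max(d, 0), arr.shape[i] + min(d, 0)) for i, d in enumerate((dx, dy, dz))
        )
        dst = tuple(
            slice(max(-d, 0), arr.shape[i] + min(-d, 0)) for i, d in enumerate((dx, dy, dz))
        )
        shifted[dst] = in_b[src]
        touch |= shifted
    return np.argwhere(in_a & touch)


def measure_plane_shift(pred: LabelMap, ref: LabelMap, plane_role: str) -> float:
    """Shift of one separating plane between a prediction and a reference.

    Vertical roles (MID, RHV, LHV_LLF): planes are fitted to the
    inter-segment boundary voxels of the relevant label pair in each map;
    the magnitude is the absolute signed distance (mm) from the reference
    plane, evaluated at the liver centroid's projection, to the predicted
    plane.  Horizontal roles (RPV_H, LPV_H): absolute difference of the
    median boundary slice index, in slices.

    Returns ``inf`` when the boundary is empty in either map (treated as a
    severe, unmeasurable shift by the rubric).
    """
    if plane_role not in PLANE_ROLES:
        raise ValueError(f"unknown plane role {plane_role!r}")
    group_a, group_b = PLANE_LABEL_GROUPS[plane_role]
    idx_pred = boundary_voxel_indices(pred, group_a, group_b)
    idx_ref = boundary_voxel_indices(ref, group_a, group_b)
    if len(idx_pred) == 0 or len(idx_ref) == 0:
        return math.inf

    if plane_role in HORIZONTAL_ROLES:
        return float(abs(np.median(idx_pred[:, 2]) - np.median(idx_ref[:, 2])))

    plane_pred = fit_plane(pred.world_coords(idx_pred))
    plane_ref = fit_plane(ref.world_coords(idx_ref))
    liver_idx = np.argwhere(np.asarray(ref.data) > 0)
    centroid = ref.world_coords(liver_idx).mean(axis=0)
    anchor = centroid - signed_distance(centroid, plane_ref) * plane_ref.normal
    return float(abs(signed_distance(anchor, plane_pred)))


def grade_shift(magnitude: float, plane_role: str) -> Grade:
    """Grade a plane shift: slight / moderate / severe.

    Vertical planes: <= 5 mm slight, >= 10 mm severe, between moderate.
    Horizontal planes: <= 2 slices slight, >= 5 slices severe, between
    moderate.  (The boundary values bind to slight and severe
    respectively.)
    """
    if magnitude < 0 or not np.isfinite(magnitude) and magnitude != math.inf:
        raise ValueError("magnitude must be >= 0")
    if plane_role in HORIZONTAL_ROLES:
        lo, hi = _HORIZONTAL_THRESHOLDS
    elif plane_role in PLANE_ROLES:
        lo, hi = _VERTICAL_THRESHOLDS
    else:
        raise ValueError(f"unknown plane role {plane_role!r}")
    if magnitude <= lo:
        return Grade.SLIGHT
    if magnitude >= hi:
        return Grade.SEVERE
    return Grade.MODERATE


def detect_fault(
    pred: LabelMap,
    ref: LabelMap,
    min_volume_mm3: float = 1000.0,
    min_distance_mm: float = 10.0,
) -> bool:
    """Detect an inter-segment segmentation fault.

    True iff some 26-connected component of mislabeled liver voxels (pred
    and ref both nonzero but different) has volume >= ``min_volume_mm3``
    AND its centroid lies >= ``min_distance_mm`` from every reference
    inter-segment boundary — i.e. the error cannot be explained by a
    shifted separating plane.
    """
    p = np.asarray(pred.data)
    r = np.asarray(ref.data)
    wrong = (p != r) & (p > 0) & (r > 0)
    if not wrong.any():
        return False

    # all reference inter-segment boundary voxels (any differing nonzero pair)
    boundary = np.zeros(r.shape, dtype=bool)
    liver = r > 0
    for dx, dy, dz in _SIX_NEIGHBORS:
        src = tuple(
            slice(max(d, 0), r.shape[i] + min(d, 0)) for i, d in enumerate((dx, dy, dz))
        )
        dst = tuple(
            slice(max(-d, 0), r.shape[i] + min(-d, 0)) for i, d in enumerate((dx, dy, dz))
        )
        neigh = np.zeros_like(r)
        neigh[dst] = r[src]
        boundary |= liver & (neigh > 0) & (neigh != r)
    if not boundary.any():
        return True  # mislabeled voxels but no segment boundary at all
    tree = cKDTree(ref.world_coords(np.argwhere(boundary)))

    comps, n = ndimage.label(wrong, structure=np.ones((3, 3, 3), dtype=bool))
    voxvol = ref.voxel_volume_mm3
    for lab in range(1, n + 1):
        comp_idx = np.argwhere(comps == lab)
        if len(comp_idx) * voxvol < min_volume_mm3:
            continue
        centroid = ref.world_coords(comp_idx).mean(axis=0)
        dist, _ = tree.query(centroid)
        if dist >= min_distance_mm:
            return True
    return False


def classify_quality(grades: Sequence[Grade], fault: bool) -> str:
    """Overall quality class from the five plane grades and the fault flag.

    poor     — any severe shift, or an inter-segment fault;
    good     — no moderate shift and at most two (nonzero) slight shifts,
               or exactly one moderate shift and no slight shift;
    moderate — everything else.

    ``Grade.NONE`` marks a zero-magnitude shift and is not counted.
    """
    grades = [Grade(g) for g in grades]
    if len(grades) != 5:
        raise ValueError("expected exactly 5 plane grades")
    if fault or Grade.SEVERE in grades:
        return "poor"
    n_slight = sum(g is Grade.SLIGHT for g in grades)
    n_moderate = sum(g is Grade.MODERATE for g in grades)
    if (n_moderate == 0 and n_slight <= 2) or (n_moderate == 1 and n_slight == 0):
        return "good"
    return "moderate"


def quality_report(pred: LabelMap, ref: LabelMap) -> QualityReport:
    """Full qualitative rubric for one case."""
    shifts = []
    for role in PLANE_ROLES:
        mag = measure_plane_shift(pred, ref, role)
        if mag < 1e-6:  # numerically zero plane-fit residual
            grade = Grade.NONE
        elif math.isinf(mag):
            grade = Grade.SEVERE  # unmeasurable boundary: treated as severe
        else:
            grade = grade_shift(mag, role)
        shifts.append(PlaneShift(role, mag, grade))
    fault = detect_fault(pred, ref)
    overall = classify_quality([s.grade for s in shifts], fault)
    return QualityReport(shifts=shifts, fault=fault, overall=overall)


def filter_lesions(
    lesions: Sequence[Lesion], min_diameter_mm: float = 5.0, max_count: int = 5
) -> list[Lesion]:
    """Keep lesions larger than ``min_diameter_mm``; at most the ``max_count``
    largest by diameter (ties broken by lower id)."""
    eligible = [l for l in lesions if l.diameter_mm > min_diameter_mm]
    eligible.sort(key=lambda l: (-l.diameter_mm, l.id))
    return eligible[:max_count]


def segments_under_mask(
    labels: LabelMap | np.ndarray, mask: np.ndarray, min_fraction: float = 0.1
) -> frozenset:
    """Segment set occupied by a voxel mask: every label covering at least
    ``min_fraction`` of the mask, always including the modal nonzero label
    (ties to the lower label).  Empty if the mask misses the liver."""
    arr = np.asarray(labels.data if isinstance(labels, LabelMap) else labels)
    under = arr[mask]
    if under.size == 0:
        return frozenset()
    counts = np.bincount(under.astype(np.int64), minlength=9)
    if counts[1:].sum() == 0:
        return frozenset()
    modal = int(np.argmax(counts[1:])) + 1
    out = {lab for lab in range(1, 9) if counts[lab] >= min_fraction * under.size}
    out.add(modal)
    return frozenset(out)


def localize_lesion(
    lesion: Lesion, pred: LabelMap, min_fraction: float = 0.1
) -> frozenset:
    """Assign a lesion to segments from an automated label map alone.

    The assigned set contains every label covering at least ``min_fraction``
    of the lesion's voxels, and always the modal (most frequent) nonzero
    label.  Raises :class:`UnlocalizableLesion` if no lesion voxel falls
    inside the predicted liver.
    """
    if not lesion.mask.any():
        raise UnlocalizableLesion(f"lesion {lesion.id} has an empty mask")
    assigned = segments_under_mask(pred, lesion.mask, min_fraction)
    if not assigned:
        raise UnlocalizableLesion(
            f"lesion {lesion.id} lies entirely outside the predicted liver"
        )
    lesion.assigned_segments = assigned
    return lesion.assigned_segments


def weighted_kappa(
    ratings_a: Sequence, ratings_b: Sequence, categories_ordered: Sequence
) -> float:
    """Linearly weighted Cohen's kappa for ordinal ratings.

    kappa_w = 1 - sum(w_ij O_ij) / sum(w_ij E_ij) with linear penalties
    w_ij = |i - j| / (k - 1), O the observed and E the chance-expected
    joint proportions.  Perfect agreement with zero chance disagreement
    (all ratings in one category) is returned as 1.0.
    """
    cats = list(categories_ordered)
    k = len(cats)
    if k < 2:
        raise ValueError("need at least 2 ordered categories")
    index = {c: i for i, c in enumerate(cats)}
    a = [index[r] for r in ratings_a]
    b = [index[r] for r in ratings_b]
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need two equal-length rating vectors of length >= 2")
    n = len(a)
    observed = np.zeros((k, k))
    for i, j in zip(a, b):
        observed[i, j] += 1.0 / n
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    idx = np.arange(k)
    w = np.abs(idx[:, None] - idx[None, :]) / (k - 1)
    num = float((w * observed).sum())
    den = float((w * expected).sum())
    if den == 0:
        return 1.0 if num == 0 else 0.0
    return 1.0 - num / den
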