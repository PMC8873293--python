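"""NIfTI / JSON readers and writers, dataset manifests and splitting.

Volumes travel as NIfTI (.nii / .nii.gz) with axis-aligned RAS affines;
non-axis-aligned inputs are reoriented to the closest canonical axes with
a logged warning.  Landmarks, lesions and quality reports are schema-
versioned JSON ("couinaud3d/v1") in physical mm.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .clinical import Lesion
from .geometry import LandmarkSet
from .grid import LabelMap, VolumeGrid

__all__ = [
    "SCHEMA",
    "CaseManifest",
    "read_volume",
    "write_volume",
    "read_landmarks",
    "write_landmarks",
    "read_lesions",
    "write_lesions",
    "split_dataset",
]

log = logging.getLogger(__name__)

SCHEMA = "couinaud3d/v1"
SPLITS = ("train", "val", "test")


@dataclass
class CaseManifest:
    case_id: str
    image: Path | None = None
    mask: Path | None = None
    labels: Path | None = None
    landmarks: Path | None = None
    lesions: Path | None = None
    split: str | None = None

    def __post_init__(self) -> None:
        if self.split is not None and self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")


def read_volume(path) -> VolumeGrid:
    """Load a 3D NIfTI volume; integer-typed files load as :class:`LabelMap`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    if len(img.shape) != 3:
        raise ValueError(f"{path} is {len(img.shape)}D; expected a 3D volume")
    # reorient to the closest canonical (RAS) axes if needed
    canonical = nib.as_closest_canonical(img)
    if canonical is not img and not np.allclose(canonical.affine, img.affine):
        log.warning("%s reoriented to canonical RAS axes on load", path)
    img = canonical
    affine = img.affine
    rot = affine[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-4):
        raise ValueError(f"{path}: affine is not axis-aligned after canonicalization")
    spacing = tuple(np.abs(np.diag(rot)))
    origin = tuple(affine[:3, 3])
    dtype = img.get_data_dtype()
    data = np.asarray(img.dataobj)
    if np.issubdtype(dtype, np.integer):
        return LabelMap(data.astype(np.int16), spacing, origin)
    return VolumeGrid(np.asarray(data, dtype=np.float64), spacing, origin)


def write_volume(volume: VolumeGrid, path) -> None:
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    data = np.asarray(volume.data)
    if isinstance(volume, LabelMap):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    nib.save(nib.Nifti1Image(data, affine), str(path))


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    payload = {"schema": SCHEMA, **landmarks.to_dict()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_landmarks(path) -> LandmarkSet:
    payload = json.loads(Path(path).read_text())
    return LandmarkSet.from_dict(payload)


def write_lesions(lesions: list[Lesion], path) -> None:
    payload = {"schema": SCHEMA, "lesions": [l.to_dict() for l in lesions]}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_lesions(path, grid: VolumeGrid) -> list[Lesion]:
    """Load lesions and re-rasterize their spherical masks on ``grid``."""
    payload = json.loads(Path(path).read_text())
    gx, gy, gz = grid.coordinate_grids()
    out = []
    for d in payload["lesions"]:
        c = np.asarray(d["center_mm"], dtype=float)
        r2 = (d["diameter_mm"] / 2.0) ** 2
        mask = (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2 <= r2
        out.append(
            Lesion(
                id=int(d["id"]),
                center_mm=c,
                diameter_mm=float(d["diameter_mm"]),
                mask=mask,
                true_segments=frozenset(d.get("true_segments", [])),
                hyper=bool(d.get("hyper", False)),
            )
        )
    return out


def split_dataset(
    manifests: list[CaseManifest],
    fractions: tuple[float, float, float] = (0.54, 0.23, 0.23),
    seed: int = 0,
) -> list[CaseManifest]:
    """Seeded shuffle then contiguous train/val/test split.

    Default fractions 0.54/0.23/0.23 mirror a conventional roughly
    54/23/23 development split.  Returns new manifests with split tags.
    """
    if not manifests:
        raise ValueError("empty manifest list")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(manifests))
    n = len(manifests)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_val = min(n_val, n - n_train)
    tagged = []
    for rank, idx in enumerate(order):
        split = "train" if rank < n_train else ("val" if rank < n_train + n_val else "test")
        m = manifests[idx]
        tagged.append(
            CaseManifest(
                case_id=m.case_id, image=m.image, mask=m.mask, labels=m.labels,
                landmarks=m.landmarks, lesions=m.lesions, split=split,
            )
        )
    return tagged
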