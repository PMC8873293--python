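"""Input pipeline: spacing normalization, grayscale z-normalization, and
sliding-window patch extraction / fusion.

Volumes are first resampled to a common voxel spacing (linear for images,
nearest-neighbor for label maps), then z-scored over the whole volume
after percentile clipping, and finally tiled into fixed-shape patches for
the network; overlapping patch probabilities are fused by uniform
averaging.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk

from .grid import LabelMap, VolumeGrid

__all__ = [
    "PreprocessConfig",
    "DegenerateInputError",
    "resample_to_spacing",
    "zscore_normalize",
    "sliding_window_starts",
    "sliding_window_patches",
    "fuse_patch_predictions",
]


class DegenerateInputError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    """Defaults: 1.5 x 1.5 x 3.0 mm target spacing (the acquisition regime),
    160^3 patches, 50% overlap, [0.5, 99.5] percentile clipping."""

    target_spacing_mm: tuple[float, float, float] = (1.5, 1.5, 3.0)
    patch_shape: tuple[int, int, int] = (160, 160, 160)
    patch_overlap_fraction: float = 0.5
    clip_percentiles: tuple[float, float] = (0.5, 99.5)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target spacing must be positive")
        if any(p <= 0 for p in self.patch_shape):
            raise ValueError("patch_shape must be positive")
        if not 0.0 <= self.patch_overlap_fraction < 1.0:
            raise ValueError("patch_overlap_fraction must lie in [0, 1)")


def _to_sitk(volume: VolumeGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.asarray(volume.data).T))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    return img


def resample_to_spacing(
    volume: VolumeGrid,
    target_spacing_mm,
    interpolation: str = "linear",
) -> VolumeGrid:
    """Resample to ``target_spacing_mm`` preserving physical extent.

    ``interpolation`` is ``"linear"`` (images) or ``"nearest"`` (label
    maps).  The output grid size is ``round(n * old / new)`` per axis, so
    the extent is preserved to within one output voxel.
    """
    target = tuple(float(s) for s in target_spacing_mm)
    if any(s <= 0 for s in target):
        raise ValueError(f"non-positive target spacing {target}")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if np.allclose(target, volume.spacing):
        return volume.with_data(np.asarray(volume.data).copy())

    new_shape = tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(volume.shape, volume.spacing, target)
    )
    interp = sitk.sitkLinear if interpolation == "linear" else sitk.sitkNearestNeighbor
    res = sitk.Resample(
        _to_sitk(volume),
        [int(n) for n in new_shape],
        sitk.Transform(),
        interp,
        tuple(volume.origin),
        target,
        np.eye(3).flatten().tolist(),
        0.0,
        sitk.sitkUnknown,
        True,  # nearest-neighbor extrapolation at the half-voxel rim
    )
    data = sitk.GetArrayFromImage(res).T
    if isinstance(volume, LabelMap):
        return LabelMap(np.ascontiguousarray(data).astype(volume.data.dtype), target, volume.origin)
    return VolumeGrid(np.ascontiguousarray(data), target, volume.origin)


def zscore_normalize(
    volume: VolumeGrid, clip_percentiles: tuple[float, float] | None = (0.5, 99.5)
) -> VolumeGrid:
    """Clip to percentiles, subtract the mean, divide by the SD (whole volume)."""
    data = np.asarray(volume.data, dtype=np.float64)
    if data.size <= 1:
        raise DegenerateInputError("volume must have more than one voxel")
    if clip_percentiles is not None:
        lo, hi = np.percentile(data, clip_percentiles)
        data = np.clip(data, lo, hi)
    sd = data.std()
    if sd == 0:
        raise DegenerateInputError("constant volume cannot be z-normalized")
    return volume.with_data((data - data.mean()) / sd)


def sliding_window_starts(axis_len: int, patch: int, stride: int) -> list[int]:
    """Window start offsets along one axis, final window clamped to the end."""
    if patch > axis_len:
        raise ValueError("patch longer than axis")
    starts = list(range(0, axis_len - patch + 1, max(stride, 1)))
    if starts[-1] != axis_len - patch:
        starts.append(axis_len - patch)
    return starts


def sliding_window_patches(
    volume: np.ndarray, patch_shape, overlap_fraction: float = 0.5
):
    """Tile a volume into fixed-shape windows.

    Returns ``(patches, padded_shape, pad_before)`` where ``patches`` is a
    list of ``(array, offset)`` with offsets on the (possibly zero-padded)
    grid.  A volume smaller than the patch is zero-padded symmetrically.
    The union of windows covers every padded voxel.
    """
    arr = np.asarray(volume)
    patch = tuple(int(p) for p in patch_shape)
    pad_before = []
    pad = []
    for n, p in zip(arr.shape, patch):
        deficit = max(0, p - n)
        before = deficit // 2
        pad_before.append(before)
        pad.append((before, deficit - before))
    if any(b + a for b, a in pad):
        arr = np.pad(arr, pad, mode="constant")

    strides = [max(1, int(round(p * (1.0 - overlap_fraction)))) for p in patch]
    starts = [
        sliding_window_starts(n, p, s) for n, p, s in zip(arr.shape, patch, strides)
    ]
    patches = []
    for offset in itertools.product(*starts):
        sl = tuple(slice(o, o + p) for o, p in zip(offset, patch))
        patches.append((arr[sl], offset))
    return patches, arr.shape, tuple(pad_before)


def fuse_patch_predictions(patches, full_shape) -> np.ndarray:
    """Average per-class probability patches into a full volume.

    ``patches`` is an iterable of ``(probs, offset)`` with ``probs`` of
    shape (C, px, py, pz).  Every voxel must be covered; the fused
    probabilities are renormalized to sum to 1 per voxel.  Patches are
    accumulated in offset order so the result is independent of input
    ordering.
    """
    patches = sorted(patches, key=lambda po: tuple(po[1]))
    if not patches:
        raise ValueError("no patches to fuse")
    n_classes = patches[0][0].shape[0]
    acc = np.zeros((n_classes, *full_shape), dtype=np.float64)
    count = np.zeros(full_shape, dtype=np.int32)
    for probs, offset in patches:
        sl = tuple(slice(o, o + s) for o, s in zip(offset, probs.shape[1:]))
        acc[(slice(None), *sl)] += probs
        count[sl] += 1
    if (count == 0).any():
        raise RuntimeError("internal error: voxel covered by no patch")
    acc /= count
    total = acc.sum(axis=0)
    np.divide(acc, total, out=acc, where=total > 0)
    return acc
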