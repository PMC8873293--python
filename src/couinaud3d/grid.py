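"""Volume containers: a 3D scalar field with voxel-spacing metadata.

Axis convention is RAS-like and axis-aligned: array axis 0 = x (patient
right), axis 1 = y (anterior), axis 2 = z (superior).  World coordinates of
voxel centers are ``origin + index * spacing`` (mm).  Readers must reorient
non-axis-aligned volumes on load (see :mod:`couinaud3d.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["VolumeGrid", "LabelMap"]


@dataclass
class VolumeGrid:
    """A 3D scalar field plus physical geometry.

    Parameters
    ----------
    data
        3D array indexed (x, y, z).
    spacing
        Per-axis voxel size in mm.
    origin
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must have length 3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    # -- geometry helpers -------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel-center ``indices`` (..., 3)."""
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinate arrays broadcastable to ``shape``."""
        ax = []
        for a in range(3):
            c = self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            shp = [1, 1, 1]
            shp[a] = self.shape[a]
            ax.append(c.reshape(shp))
        return ax[0], ax[1], ax[2]

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        """Same geometry, new voxel data."""
        return replace(self, data=data)

    def same_grid(self, other: "VolumeGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )


@dataclass
class LabelMap(VolumeGrid):
    """Integer :class:`VolumeGrid` carrying Couinaud labels.

    Label 0 is background (outside the liver); labels 1-8 are segments
    S1-S8 (S1 caudate, S2/S3 left lateral, S4 left medial, S5/S8 right
    anterior, S6/S7 right posterior).
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelMap data must be integer typed")
        if self.data.size and (self.data.min() < 0 or self.data.max() > 8):
            raise ValueError("labels must lie in {0, ..., 8}")
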