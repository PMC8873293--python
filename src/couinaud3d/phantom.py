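"""Synthetic portal-venous-phase liver MR phantoms.

Every downstream stage (plane-based labeling, network training, metrics,
clinical rubric) is exercised on these phantoms, so no imaging data needs
to be downloaded.  A phantom emulates the geometric and radiometric
features a PVP liver MR volume presents to a segmentation pipeline:

* a smooth, connected liver — an ellipsoid radially modulated by a seeded
  low-order spherical-harmonic field;
* bright tubular vessels (IVC, the three hepatic veins, portal branch
  blobs) laid along idealized landmark polylines radiating from the IVC;
* a gallbladder-fossa vertex on the inferior surface, a left longitudinal
  fissure, and a venous-ligament fissure curve delimiting the caudate;
* optional hypo-/hyper-intense spherical lesions with recorded true
  segment sets;
* anisotropic voxels, additive Gaussian noise and a smooth multiplicative
  bias field.

Intensity units are arbitrary (MR has none): background 40, parenchyma
100, vessels 160, hypo-lesions 60, hyper-lesions 150.

Ground-truth Couinaud labels come from
:func:`couinaud3d.geometry.assign_couinaud_labels` applied to the
generated landmarks — the same five-plane protocol used everywhere else.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .clinical import Lesion
from .geometry import LandmarkSet, assign_couinaud_labels
from .grid import LabelMap, VolumeGrid

__all__ = [
    "PhantomConfig",
    "PhantomCase",
    "ConfigurationError",
    "LesionPlacementError",
    "INTENSITY",
    "generate_liver_mask",
    "generate_landmarks",
    "insert_lesions",
    "make_lesion",
    "render_intensities",
    "generate_case",
]

INTENSITY = {
    "background": 40.0,
    "parenchyma": 100.0,
    "vessel": 160.0,
    "lesion_hypo": 60.0,
    "lesion_hyper": 150.0,
}


class ConfigurationError(ValueError):
    pass


class LesionPlacementError(RuntimeError):
    pass


@dataclass
class PhantomConfig:
    """Study conditions for one synthetic case.

    Defaults give a 96 x 96 x 64 grid at 2 x 2 x 3 mm (192 mm cube of
    physical extent) — the anisotropic, thick-slice regime of abdominal
    PVP acquisitions — with mild shape irregularity and moderate noise.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)
    liver_radius_mm: tuple[float, float, float] = (70.0, 55.0, 62.0)
    shape_irregularity: float = 0.3
    vessel_radius_mm: float = 3.0
    lesion_count: int = 0
    lesion_diameter_range_mm: tuple[float, float] = (6.0, 30.0)
    lesion_straddle: bool = False
    noise_sigma: float = 8.0
    bias_field_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 8 for n in self.grid_shape):
            raise ConfigurationError("grid_shape axes must be >= 8 voxels")
        if any(s <= 0 for s in self.spacing_mm) or any(r <= 0 for r in self.liver_radius_mm):
            raise ConfigurationError("spacings and radii must be positive")
        if not 0.0 <= self.shape_irregularity <= 1.0:
            raise ConfigurationError("shape_irregularity must lie in [0, 1]")
        if self.vessel_radius_mm <= 0:
            raise ConfigurationError("vessel_radius_mm must be positive")
        if self.lesion_count < 0:
            raise ConfigurationError("lesion_count must be >= 0")
        lo, hi = self.lesion_diameter_range_mm
        if lo <= 0 or lo > hi:
            raise ConfigurationError("lesion_diameter_range_mm must satisfy 0 < min <= max")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be >= 0")
        if not 0.0 <= self.bias_field_amplitude < 1.0:
            raise ConfigurationError("bias_field_amplitude must lie in [0, 1)")
        # liver (with maximal modulation and jitter headroom) must fit with
        # a >= 2-voxel margin
        half_extent = [n * s / 2.0 for n, s in zip(self.grid_shape, self.spacing_mm)]
        max_r = [
            r * 1.08 * (1.0 + 0.15 * self.shape_irregularity) + 4.0
            for r in self.liver_radius_mm
        ]
        for r, h, s in zip(max_r, half_extent, self.spacing_mm):
            if r > h - 2.0 * s:
                raise ConfigurationError(
                    "liver does not fit in the grid with a 2-voxel margin"
                )

    @property
    def center_mm(self) -> np.ndarray:
        return np.array(
            [(n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.spacing_mm)]
        )


@dataclass
class PhantomCase:
    image: VolumeGrid
    liver_mask: VolumeGrid
    labels: LabelMap
    landmarks: LandmarkSet
    lesions: list[Lesion]
    config: PhantomConfig


def _rng(config: PhantomConfig, stream: int) -> np.random.Generator:
    """Independent deterministic stream per generation stage."""
    return np.random.default_rng([int(config.seed) & 0x7FFFFFFF, stream])


def _empty_grid(config: PhantomConfig, dtype=np.float64) -> VolumeGrid:
    return VolumeGrid(
        np.zeros(config.grid_shape, dtype=dtype), config.spacing_mm, (0.0, 0.0, 0.0)
    )


def generate_liver_mask(config: PhantomConfig) -> VolumeGrid:
    """Binary liver mask: ellipsoid with smooth seeded radial modulation.

    The implicit surface is ``|u| = 1 + 0.15 * irregularity * S(dir)``
    where ``u`` is the radius-normalized offset from the liver center and
    ``S`` is a unit-normalized combination of degree-1/2 spherical
    harmonics.  The modulated shape is star-convex about the center, hence
    a single connected component.
    """
    rng = _rng(config, 0)
    center = config.center_mm + np.append(rng.uniform(-4.0, 4.0, size=2), 0.0)
    radii = np.asarray(config.liver_radius_mm) * rng.uniform(0.92, 1.08, size=3)

    grid = _empty_grid(config)
    gx, gy, gz = grid.coordinate_grids()
    u = np.stack(
        np.broadcast_arrays(
            (gx - center[0]) / radii[0],
            (gy - center[1]) / radii[1],
            (gz - center[2]) / radii[2],
        ),
        axis=-1,
    )
    r = np.linalg.norm(u, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(r[..., None] > 1e-9, u / np.maximum(r[..., None], 1e-9), 0.0)
    dx, dy, dz = d[..., 0], d[..., 1], d[..., 2]

    coeffs = rng.standard_normal(8)
    basis = [dx, dy, dz, dx * dy, dy * dz, dx * dz, dx * dx - dy * dy, 3 * dz * dz - 1.0]
    s_field = sum(c * b for c, b in zip(coeffs, basis))
    peak = np.abs(s_field).max()
    if peak > 0:
        s_field = s_field / peak
    mask = r <= 1.0 + 0.15 * config.shape_irregularity * s_field

    # margin check on the realized shape
    if (
        mask[:2].any() or mask[-2:].any()
        or mask[:, :2].any() or mask[:, -2:].any()
        or mask[:, :, :2].any() or mask[:, :, -2:].any()
    ):
        raise ConfigurationError("liver touches the 2-voxel grid margin")
    return grid.with_data(mask.astype(np.uint8))


def _march_extent(mask: VolumeGrid, start: np.ndarray, direction: np.ndarray) -> float:
    """Distance (mm) from ``start`` along ``direction`` to the last in-liver point."""
    arr = np.asarray(mask.data) > 0
    spacing = np.asarray(mask.spacing)
    step = float(min(spacing)) / 2.0
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    last_inside = 0.0
    for t in np.arange(step, 300.0, step):
        p = start + t * d
        idx = np.round((p - np.asarray(mask.origin)) / spacing).astype(int)
        if (idx < 0).any() or (idx >= np.asarray(arr.shape)).any():
            break
        if arr[tuple(idx)]:
            last_inside = t
    return last_inside


def _inside(mask: VolumeGrid, p: np.ndarray) -> bool:
    idx = np.round((p - np.asarray(mask.origin)) / np.asarray(mask.spacing)).astype(int)
    if (idx < 0).any() or (idx >= np.asarray(mask.shape)).any():
        return False
    return bool(np.asarray(mask.data)[tuple(idx)] > 0)


def _pull_inside(mask: VolumeGrid, p: np.ndarray, anchor: np.ndarray) -> np.ndarray:
    """Shrink ``p`` toward ``anchor`` until it falls inside the mask."""
    q = p.copy()
    for _ in range(60):
        if _inside(mask, q):
            return q
        q = anchor + 0.92 * (q - anchor)
    return q


def generate_landmarks(config: PhantomConfig, liver_mask: VolumeGrid) -> LandmarkSet:
    """Idealized vascular/fissure landmarks consistent with the liver mask.

    The IVC runs vertically near the liver's posterior midline; the
    three hepatic-vein polylines radiate from its midpoint at seeded
    azimuthal angles (right ~25 deg, middle ~70 deg, left ~115 deg from
    patient-right), each lying exactly in its vertical dividing plane; the
    left longitudinal fissure continues the left divider inferiorly; the
    venous-ligament curve hugs the IVC antero-laterally.
    """
    if not np.asarray(liver_mask.data).any():
        raise ConfigurationError("liver mask is empty")
    rng = _rng(config, 1)
    arr = np.asarray(liver_mask.data) > 0
    idx = np.argwhere(arr)
    pts = liver_mask.world_coords(idx)
    c = pts.mean(axis=0)
    rx, ry, rz = config.liver_radius_mm
    z_top, z_bot = pts[:, 2].max(), pts[:, 2].min()

    phi_rhv, phi_mid, phi_lhv = (
        np.deg2rad([25.0, 70.0, 115.0]) + np.deg2rad(rng.uniform(-4.0, 4.0, size=3))
    )

    # IVC near the posterior midline: the left lobe extends well past it
    ivc_xy = np.array([c[0] - 0.25 * rx, c[1] - 0.50 * ry]) + rng.uniform(-3, 3, size=2)
    ivc_z = np.linspace(c[2] - 0.8 * rz, c[2] + 0.8 * rz, 9)
    ivc = np.column_stack([np.full(9, ivc_xy[0]), np.full(9, ivc_xy[1]), ivc_z])
    m = np.array([ivc_xy[0], ivc_xy[1], ivc_z.mean()])

    def vein(phi: float, z_lo_frac: float, z_hi_frac: float, n: int = 10) -> np.ndarray:
        d = np.array([math.cos(phi), math.sin(phi), 0.0])
        extent = _march_extent(liver_mask, m, d)
        ts = np.linspace(0.15, 0.85, n) * max(extent, 10.0)
        # gentle in-plane vertical bow: keeps the polyline exactly in its
        # vertical plane but off any single line, so a plane fit to the
        # polyline alone is well conditioned
        bow = 0.08 * rz * np.sin(np.linspace(0.0, math.pi, n))
        zs = m[2] + np.linspace(z_lo_frac, z_hi_frac, n) * rz + bow
        pts_v = np.column_stack([m[0] + ts * d[0], m[1] + ts * d[1], zs])
        return np.array([_pull_inside(liver_mask, p, np.array([m[0], m[1], p[2]])) for p in pts_v])

    # hepatic veins drain superiorly toward the IVC; sample each with real
    # vertical spread so the fitted plane is well conditioned
    mhv = vein(phi_mid, -0.30, 0.45)
    rhv = vein(phi_rhv, -0.30, 0.45)

    z_rpv = float(c[2] - 0.08 * rz + rng.uniform(-4.0, 4.0))
    z_lpv = float(c[2] + rng.uniform(-4.0, 4.0))

    # left divider: LHV above the left-portal level, fissure below it;
    # clamping z and re-pulling toward the IVC axis keeps both in-plane
    lhv = vein(phi_lhv, 0.06, 0.45)
    llf = vein(phi_lhv, -0.45, -0.06)
    lhv[:, 2] = np.maximum(lhv[:, 2], z_lpv + 2.0)
    llf[:, 2] = np.minimum(llf[:, 2], z_lpv - 2.0)
    lhv = np.array([_pull_inside(liver_mask, p, np.array([m[0], m[1], p[2]])) for p in lhv])
    llf = np.array([_pull_inside(liver_mask, p, np.array([m[0], m[1], p[2]])) for p in llf])

    # gallbladder-fossa vertex: in the MID plane, on the inferior surface
    d_mid = np.array([math.cos(phi_mid), math.sin(phi_mid), 0.0])
    ext = _march_extent(liver_mask, m, d_mid)
    gb_xy = m[:2] + 0.8 * ext * d_mid[:2]
    col = np.round(
        (gb_xy - np.asarray(liver_mask.origin[:2])) / np.asarray(liver_mask.spacing[:2])
    ).astype(int)
    col = np.clip(col, 0, np.asarray(arr.shape[:2]) - 1)
    zcol = np.where(arr[col[0], col[1], :])[0]
    if len(zcol) == 0:
        raise ConfigurationError("gallbladder column misses the liver")
    gb_z = liver_mask.origin[2] + zcol.min() * liver_mask.spacing[2]
    gb_vertex = np.array([gb_xy[0], gb_xy[1], gb_z])

    rpv = np.array([c[0] + 0.30 * rx, c[1] - 0.10 * ry, z_rpv])
    rpv = _pull_inside(liver_mask, rpv, np.array([c[0], c[1], z_rpv]))
    d_lhv = np.array([math.cos(phi_lhv), math.sin(phi_lhv), 0.0])
    lpv_sag = m + 0.45 * _march_extent(liver_mask, m, d_lhv) * d_lhv
    lpv_sag[2] = z_lpv
    lpv_sag = _pull_inside(liver_mask, lpv_sag, np.array([c[0], c[1], z_lpv]))
    lpv_sag[2] = z_lpv

    vl_z = np.linspace(c[2] - 0.15 * rz, c[2] + 0.45 * rz, 7)
    bow = 4.0 * np.sin(np.linspace(0.0, math.pi, 7))  # gentle anterior bow
    vl = np.column_stack(
        [
            np.full(7, ivc_xy[0] - 20.0) + rng.uniform(-2, 2, size=7),
            np.full(7, ivc_xy[1] + 16.0) + bow + rng.uniform(-2, 2, size=7),
            vl_z,
        ]
    )
    vl = np.array(
        [_pull_inside(liver_mask, p, np.array([c[0], c[1], p[2]])) for p in vl]
    )

    return LandmarkSet(
        ivc=ivc,
        mhv=mhv,
        rhv=rhv,
        lhv=lhv,
        llf=llf,
        gb_vertex=gb_vertex,
        rpv=rpv,
        lpv_sag=lpv_sag,
        vl_fissure=vl,
        ivc_radius_mm=5.0,
    )


def make_lesion(
    labels: LabelMap, center_mm: np.ndarray, diameter_mm: float, lesion_id: int,
    hyper: bool = False,
) -> Lesion:
    """Rasterize a spherical lesion and record its true segment set.

    Truth uses the same occupancy rule as lesion localization (every label
    covering >= 10% of the lesion, plus the modal label), so a perfect
    label map localizes every lesion correctly and one-voxel spills do not
    flip the call.
    """
    from .clinical import segments_under_mask

    center_mm = np.asarray(center_mm, dtype=float)
    gx, gy, gz = labels.coordinate_grids()
    r2 = (diameter_mm / 2.0) ** 2
    mask = (gx - center_mm[0]) ** 2 + (gy - center_mm[1]) ** 2 + (gz - center_mm[2]) ** 2 <= r2
    return Lesion(
        id=lesion_id, center_mm=center_mm, diameter_mm=float(diameter_mm),
        mask=mask, true_segments=segments_under_mask(labels, mask), hyper=hyper,
    )


def insert_lesions(
    liver_mask: VolumeGrid, labels: LabelMap, config: PhantomConfig
) -> list[Lesion]:
    """Place ``config.lesion_count`` spherical lesions inside the liver.

    Centers are drawn uniformly over liver voxels; with
    ``config.lesion_straddle`` every other lesion is centered on an
    inter-segment boundary voxel so that it deliberately straddles a
    dividing plane.  Raises :class:`LesionPlacementError` after bounded
    retries.
    """
    if config.lesion_count == 0:
        return []
    rng = _rng(config, 2)
    arr = np.asarray(labels.data)
    liver_idx = np.argwhere(arr > 0)
    if len(liver_idx) == 0:
        raise LesionPlacementError("cannot place lesions: empty liver")

    boundary_idx = None
    if config.lesion_straddle:
        from .clinical import boundary_voxel_indices  # local import avoids cycle at module load

        groups = [({5, 8}, {6, 7}), ({2, 3, 4}, {5, 6, 7, 8}), ({7, 8}, {5, 6})]
        parts = [boundary_voxel_indices(labels, a, b) for a, b in groups]
        parts = [p for p in parts if len(p)]
        if parts:
            boundary_idx = np.vstack(parts)

    lo, hi = config.lesion_diameter_range_mm
    lesions: list[Lesion] = []
    for i in range(config.lesion_count):
        diameter = float(rng.uniform(lo, hi))
        placed = False
        for _ in range(100):
            if config.lesion_straddle and boundary_idx is not None and i % 2 == 0:
                pick = boundary_idx[rng.integers(len(boundary_idx))]
            else:
                pick = liver_idx[rng.integers(len(liver_idx))]
            center = labels.world_coords(pick)
            lesion = make_lesion(labels, center, diameter, i, hyper=bool(rng.random() < 0.3))
            if lesion.true_segments:
                lesions.append(lesion)
                placed = True
                break
        if not placed:
            raise LesionPlacementError(f"could not place lesion {i} inside the liver")
    return lesions


def _paint_tube(
    canvas: np.ndarray, grid: VolumeGrid, polyline: np.ndarray, radius_mm: float
) -> None:
    """Mark voxels within ``radius_mm`` of any polyline segment (in place)."""
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    shape = np.asarray(canvas.shape)
    for p, q in zip(polyline[:-1], polyline[1:]):
        lo = np.floor((np.minimum(p, q) - radius_mm - origin) / spacing).astype(int)
        hi = np.ceil((np.maximum(p, q) + radius_mm - origin) / spacing).astype(int) + 1
        lo = np.clip(lo, 0, shape)
        hi = np.clip(hi, 0, shape)
        if (hi <= lo).any():
            continue
        ax = [origin[a] + np.arange(lo[a], hi[a]) * spacing[a] for a in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        v = np.stack([X - p[0], Y - p[1], Z - p[2]], axis=-1)
        seg = q - p
        seg_len2 = float(seg @ seg)
        t = np.clip((v @ seg) / seg_len2, 0.0, 1.0) if seg_len2 > 0 else 0.0
        closest = np.asarray(t)[..., None] * seg
        dist2 = ((v - closest) ** 2).sum(axis=-1)
        sub = canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub |= dist2 <= radius_mm**2


def render_intensities(
    liver_mask: VolumeGrid,
    landmarks: LandmarkSet,
    lesions: list[Lesion],
    config: PhantomConfig,
) -> VolumeGrid:
    """Piecewise-constant tissue image + bias field + Gaussian noise."""
    mask = np.asarray(liver_mask.data) > 0
    img = np.full(mask.shape, INTENSITY["background"], dtype=np.float64)
    img[mask] = INTENSITY["parenchyma"]

    vessels = np.zeros(mask.shape, dtype=bool)
    for poly in (landmarks.ivc, landmarks.mhv, landmarks.rhv, landmarks.lhv):
        _paint_tube(vessels, liver_mask, poly, config.vessel_radius_mm)
    for pt in (landmarks.rpv, landmarks.lpv_sag):
        ball = np.vstack([pt, pt + np.array([0.0, 0.0, 1e-3])])
        _paint_tube(vessels, liver_mask, ball, 1.4 * config.vessel_radius_mm)
    img[vessels] = INTENSITY["vessel"]

    for lesion in lesions:
        img[lesion.mask] = (
            INTENSITY["lesion_hyper"] if lesion.hyper else INTENSITY["lesion_hypo"]
        )

    if config.bias_field_amplitude > 0:
        rng_bias = _rng(config, 3)
        rough = rng_bias.standard_normal(mask.shape)
        smooth = ndimage.gaussian_filter(rough, sigma=[n / 6.0 for n in mask.shape])
        peak = np.abs(smooth).max()
        if peak > 0:
            smooth /= peak
        img *= 1.0 + config.bias_field_amplitude * smooth

    if config.noise_sigma > 0:
        rng_noise = _rng(config, 4)
        img += rng_noise.normal(0.0, config.noise_sigma, size=mask.shape)

    return liver_mask.with_data(img)


def generate_case(config: PhantomConfig) -> PhantomCase:
    """Full phantom: mask -> landmarks -> labels -> lesions -> image.  Pure."""
    liver_mask = generate_liver_mask(config)
    landmarks = generate_landmarks(config, liver_mask)
    labels = assign_couinaud_labels(liver_mask, landmarks)
    lesions = insert_lesions(liver_mask, labels, config)
    image = render_intensities(liver_mask, landmarks, lesions, config)
    return PhantomCase(
        image=image, liver_mask=liver_mask, labels=labels,
        landmarks=landmarks, lesions=lesions, config=config,
    )
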