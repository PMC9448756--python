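"""Synthetic OCT-like choroid phantoms with analytic ground truth.

Tube networks are rendered in *acquired* polarity — bright stroma, dark
vessel lumina — so the downstream inversion/enhancement chain is exercised
end-to-end.  Every tube carries closed-form truth values (arc length,
volume, lateral surface area, diameter) against which pipeline estimates
can be scored.

Physical convention: the centre of voxel ``(i, j, k)`` sits at
``((i + 0.5) dx, (j + 0.5) dy, (k + 0.5) dz)`` mm.  A voxel belongs to a
tube iff its centre lies within the tube radius of the centreline polyline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .choroid_mask import ChoroidMask
from .volume_io import VoxelGrid, VoxelSpacing

__all__ = [
    "TubeSpec",
    "PhantomTruth",
    "straight_tube",
    "helix_tube",
    "make_slab_choroid",
    "render_tubes",
]


@dataclass
class TubeSpec:
    """One tube: a 3D centreline polyline (mm) plus radius and contrast."""

    centerline: np.ndarray  # (N, 3) points in mm, (x, y, z)
    radius: float  # mm
    intensity_contrast: float = 1.0  # in (0, 1]

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        if self.centerline.ndim != 2 or self.centerline.shape[1] != 3 or len(self.centerline) < 2:
            raise ValueError("centerline must be an (N>=2, 3) array of mm coordinates")
        if not (self.radius > 0):
            raise ValueError("radius must be positive")
        if not (0 < self.intensity_contrast <= 1):
            raise ValueError("intensity_contrast must be in (0, 1]")

    @property
    def length(self) -> float:
        """Polyline arc length in mm."""
        return float(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1).sum())

    @property
    def volume(self) -> float:
        """Analytic cylinder volume pi r^2 L in mm^3."""
        return float(np.pi * self.radius**2 * self.length)

    @property
    def lateral_surface(self) -> float:
        """Analytic lateral surface 2 pi r L in mm^2 (end caps excluded)."""
        return float(2.0 * np.pi * self.radius * self.length)

    @property
    def end_cap_area(self) -> float:
        """Combined area of the two end caps, 2 pi r^2 (mm^2)."""
        return float(2.0 * np.pi * self.radius**2)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


def straight_tube(p0, p1, radius: float, contrast: float = 1.0) -> TubeSpec:
    """Straight cylinder from ``p0`` to ``p1`` (mm)."""
    return TubeSpec(np.array([p0, p1], dtype=float), radius, contrast)


def helix_tube(
    center_xz: tuple[float, float],
    y_mm: float,
    helix_radius: float,
    pitch: float,
    turns: float,
    tube_radius: float,
    contrast: float = 1.0,
    samples_per_turn: int = 256,
) -> tuple[TubeSpec, float]:
    """Helix winding about the depth axis; returns (tube, analytic arc length).

    Parametrisation: ``(cx + R cos t, y + pitch * t / 2pi, cz + R sin t)``
    for ``t`` in ``[0, 2 pi turns]``; exact length is
    ``2 pi turns * sqrt(R^2 + (pitch / 2 pi)^2)``.
    """
    n = max(int(samples_per_turn * turns), 8)
    t = np.linspace(0.0, 2.0 * np.pi * turns, n + 1)
    cx, cz = center_xz
    pts = np.stack(
        [cx + helix_radius * np.cos(t), y_mm + pitch * t / (2.0 * np.pi), cz + helix_radius * np.sin(t)],
        axis=1,
    )
    exact_length = 2.0 * np.pi * turns * float(np.hypot(helix_radius, pitch / (2.0 * np.pi)))
    return TubeSpec(pts, tube_radius, contrast), exact_length


@dataclass
class PhantomTruth:
    """Analytic ground truth for one rendered phantom."""

    tubes: list[dict] = field(default_factory=list)
    slab_volume: float = 0.0  # mm^3
    thickness_map: np.ndarray | None = None  # en-face, mm
    overlapping: bool = False

    @property
    def total_length(self) -> float:
        return sum(t["length"] for t in self.tubes)

    @property
    def total_volume(self) -> float:
        return sum(t["volume"] for t in self.tubes)

    @property
    def total_lateral_surface(self) -> float:
        return sum(t["lateral_surface"] for t in self.tubes)

    def as_records(self) -> list[dict]:
        return [dict(t) for t in self.tubes]


def make_slab_choroid(
    shape: tuple[int, int, int],
    spacing: VoxelSpacing,
    upper_depth,
    thickness,
) -> ChoroidMask:
    """Build a slab-shaped choroid mask from an upper depth and a thickness.

    ``upper_depth`` and ``thickness`` are given in mm, either as scalars or
    en-face (x, z) fields.  The slab occupies depth voxels whose index lies
    in ``[upper_depth/dy, (upper_depth+thickness)/dy)``.
    """
    nx, ny, nz = shape
    upper = np.broadcast_to(np.asarray(upper_depth, dtype=float), (nx, nz)).copy()
    thick = np.broadcast_to(np.asarray(thickness, dtype=float), (nx, nz)).copy()
    if np.any(thick <= 0):
        raise ValueError("slab thickness must be strictly positive everywhere")
    upper_idx = upper / spacing.dy
    lower_idx = (upper + thick) / spacing.dy
    if np.any(upper_idx < 0) or np.any(lower_idx > ny):
        raise ValueError(
            f"slab [{upper_idx.min():.1f}, {lower_idx.max():.1f}) voxels does not fit in depth {ny}"
        )
    return ChoroidMask.from_surfaces(upper_idx, lower_idx, depth=ny, spacing=spacing)


def _voxelize_tube(tube: TubeSpec, shape, spacing: VoxelSpacing) -> np.ndarray:
    """Boolean volume of voxels whose centre is within tube.radius of the polyline."""
    nx, ny, nz = shape
    d = np.array([spacing.dx, spacing.dy, spacing.dz])
    inside = np.zeros(shape, dtype=bool)
    pts = tube.centerline
    r = tube.radius
    for a, b in zip(pts[:-1], pts[1:]):
        lo = np.minimum(a, b) - r
        hi = np.maximum(a, b) + r
        # voxel index ranges whose centres may fall inside this segment's capsule
        i0 = np.maximum(np.floor(lo / d - 0.5).astype(int), 0)
        i1 = np.minimum(np.ceil(hi / d - 0.5).astype(int) + 1, [nx, ny, nz])
        if np.any(i0 >= i1):
            continue
        xs = (np.arange(i0[0], i1[0]) + 0.5) * d[0]
        ys = (np.arange(i0[1], i1[1]) + 0.5) * d[1]
        zs = (np.arange(i0[2], i1[2]) + 0.5) * d[2]
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        P = np.stack([X, Y, Z], axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            closest = a
        else:
            t = np.clip(((P - a) @ ab) / denom, 0.0, 1.0)
            closest = a + t[..., None] * ab
        dist2 = np.sum((P - closest) ** 2, axis=-1)
        inside[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] |= dist2 <= r * r
    return inside


def render_tubes(
    tubes: list[TubeSpec],
    mask: ChoroidMask,
    noise_sigma: float = 0.0,
    seed: int = 0,
    background: float = 0.8,
    speckle: bool = False,
) -> tuple[VoxelGrid, PhantomTruth]:
    """Render tubes as dark silhouettes on a bright stromal background.

    Returns an 8-bit acquired-polarity volume and the analytic truth table.
    Noise is additive Gaussian on the [0, 1] intensity scale (multiplicative
    speckle-like noise behind the ``speckle`` flag), clipped to range;
    output is deterministic for a fixed ``seed``.
    """
    shape = mask.mask.shape
    spacing = mask.spacing
    d = np.array([spacing.dx, spacing.dy, spacing.dz])
    extent = np.array(shape) * d

    for i, tube in enumerate(tubes):
        if np.any(tube.centerline < 0) or np.any(tube.centerline > extent):
            raise ValueError(f"tube {i} escapes the volume bounds (extent {extent} mm)")
        if tube.radius < 2.0 * max(spacing.as_tuple()):
            warnings.warn(
                f"tube {i}: radius {tube.radius} mm < 2x max spacing; phantom may be under-resolved",
                stacklevel=2,
            )

    intensity = np.full(shape, background, dtype=np.float64)
    claim = np.zeros(shape, dtype=np.uint8)
    truth = PhantomTruth(
        slab_volume=mask.cvolume_total,
        thickness_map=None
        if mask.lower_surface is None or mask.upper_surface is None
        else (mask.lower_surface - mask.upper_surface) * spacing.dy,
    )
    for i, tube in enumerate(tubes):
        lo = tube.centerline.min(axis=0) - tube.radius
        hi = tube.centerline.max(axis=0) + tube.radius
        clipped = bool(np.any(lo < 0) or np.any(hi > extent))
        if clipped:
            warnings.warn(
                f"tube {i} is clipped at the volume faces; analytic truth refers to the unclipped capsule",
                stacklevel=2,
            )
        vox = _voxelize_tube(tube, shape, spacing)
        claim += vox
        intensity[vox] = background * (1.0 - tube.intensity_contrast)
        truth.tubes.append(
            {
                "clipped": clipped,
                "tube": i,
                "length": tube.length,
                "volume": tube.volume,
                "lateral_surface": tube.lateral_surface,
                "end_cap_area": tube.end_cap_area,
                "diameter": tube.diameter,
                "radius": tube.radius,
                "voxel_count": int(vox.sum()),
            }
        )
    if np.any(claim > 1):
        truth.overlapping = True
        warnings.warn("tubes overlap; truth totals are not additive in the overlap", stacklevel=2)

    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        if speckle:
            intensity = intensity * (1.0 + noise_sigma * rng.standard_normal(shape))
        else:
            intensity = intensity + noise_sigma * rng.standard_normal(shape)
    intensity = np.clip(intensity, 0.0, 1.0)
    data = np.floor(intensity * 255.0 + 0.5).astype(np.uint8)
    return VoxelGrid(data, spacing), truth
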