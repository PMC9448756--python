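"""Fovea-centred region-of-interest grid on the en-face plane.

Five regions partition the 4.5-mm-diameter analysis circle: a central
1-mm-diameter circle (label 1) plus four quadrants of the surrounding
annulus (labels 2-5), split by the horizontal and vertical lines through
the fovea.  Label codes:

    0  outside the 4.5-mm circle
    1  centre circle
    2  upper temporal quadrant
    3  lower temporal quadrant
    4  lower nasal quadrant
    5  upper nasal quadrant

Orientation convention: x is horizontal (temporal side at smaller x for a
right eye, at larger x for a left eye), z is vertical with "upper"
(superior) at smaller z.  A pixel belongs to a region iff its centre point
does; pixels exactly on a dividing line take the smaller label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume_io import VoxelSpacing

__all__ = ["RoiGrid", "build_roi", "region_area", "REGION_NAMES", "CENTER_RADIUS_MM", "OUTER_RADIUS_MM"]

CENTER_RADIUS_MM = 0.5
OUTER_RADIUS_MM = 2.25

REGION_NAMES = {
    0: "outside",
    1: "center",
    2: "upper_temporal",
    3: "lower_temporal",
    4: "lower_nasal",
    5: "upper_nasal",
}

PARAFOVEA_REGIONS = (2, 3, 4, 5)
CIRCLE_REGIONS = (1, 2, 3, 4, 5)


@dataclass
class RoiGrid:
    """En-face integer label map with per-region physical areas."""

    labels: np.ndarray
    fovea_xz: tuple[int, int]
    spacing: VoxelSpacing
    laterality: str
    truncated: bool = False
    areas_mm2: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not self.areas_mm2:
            px = self.spacing.dx * self.spacing.dz
            self.areas_mm2 = {r: float((self.labels == r).sum()) * px for r in REGION_NAMES}

    def has_region(self, region: int) -> bool:
        return region in REGION_NAMES

    def region_mask(self, region: int) -> np.ndarray:
        if not self.has_region(region):
            raise KeyError(f"unknown region id: {region}")
        return self.labels == region


def build_roi(
    shape_xz: tuple[int, int],
    spacing: VoxelSpacing,
    fovea_xz: tuple[int, int],
    laterality: str = "right",
) -> RoiGrid:
    """Rasterize the five-region foveal grid onto an (nx, nz) en-face plane."""
    if laterality not in ("right", "left"):
        raise ValueError(f"laterality must be 'right' or 'left', got {laterality!r}")
    nx, nz = shape_xz
    fx, fz = int(fovea_xz[0]), int(fovea_xz[1])
    if not (0 <= fx < nx and 0 <= fz < nz):
        raise ValueError(f"fovea {fovea_xz} outside en-face bounds {(nx, nz)}")

    # signed en-face displacement of pixel centres from the fovea, in mm
    u = (np.arange(nx, dtype=float) - fx) * spacing.dx  # horizontal
    v = (np.arange(nz, dtype=float) - fz) * spacing.dz  # vertical
    U, V = np.meshgrid(u, v, indexing="ij")
    r2 = U * U + V * V

    labels = np.zeros((nx, nz), dtype=np.uint8)
    in_outer = r2 <= OUTER_RADIUS_MM**2
    in_center = r2 <= CENTER_RADIUS_MM**2

    # temporal side: smaller x for a right eye, larger x for a left eye
    temporal = U <= 0 if laterality == "right" else U >= 0
    nasal = U >= 0 if laterality == "right" else U <= 0
    upper = V <= 0
    lower = V >= 0

    annulus = in_outer & ~in_center
    # assign in decreasing label order so ties resolve to the smaller label
    labels[annulus & nasal & upper] = 5
    labels[annulus & nasal & lower] = 4
    labels[annulus & temporal & lower] = 3
    labels[annulus & temporal & upper] = 2
    labels[in_center] = 1

    truncated = (
        (fx * spacing.dx < OUTER_RADIUS_MM)
        or ((nx - 1 - fx) * spacing.dx < OUTER_RADIUS_MM)
        or (fz * spacing.dz < OUTER_RADIUS_MM)
        or ((nz - 1 - fz) * spacing.dz < OUTER_RADIUS_MM)
    )
    if truncated:
        warnings.warn("4.5-mm analysis circle does not fit in the scan; regions are truncated", stacklevel=2)
    return RoiGrid(labels=labels, fovea_xz=(fx, fz), spacing=spacing, laterality=laterality, truncated=truncated)


def region_area(roi: RoiGrid, region: int) -> float:
    """Physical region area (mm^2): pixel count x dx*dz."""
    if not roi.has_region(region):
        raise KeyError(f"unknown region id: {region}")
    return roi.areas_mm2[region]


def parafovea_area(roi: RoiGrid) -> float:
    return sum(roi.areas_mm2[r] for r in PARAFOVEA_REGIONS)


def circle_area(roi: RoiGrid) -> float:
    return sum(roi.areas_mm2[r] for r in CIRCLE_REGIONS)
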