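"""Choroid occupancy mask, boundary smoothing, CVolume and SFCT.

The choroid slab is delimited in depth by two en-face surfaces: the upper
(sub-RPE) border and the lower (choroid/sclera, "C/S") border, both stored
as en-face maps of fractional depth index.  The binary mask holds voxels
whose depth index lies in the half-open interval ``[upper, lower)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .volume_io import VoxelGrid, VoxelSpacing

__all__ = ["ChoroidMask", "smooth_cs_border", "compute_cvolume", "compute_sfct"]


@dataclass
class ChoroidMask:
    """Binary choroid occupancy volume plus optional boundary depth maps.

    ``mask`` is boolean, indexed (x, y, z) like its parent grid.
    ``upper_surface`` / ``lower_surface`` are (x, z) float maps of depth
    (y) index; where both are present the mask is True exactly for
    ``upper <= y < lower``.
    """

    mask: np.ndarray
    spacing: VoxelSpacing
    upper_surface: np.ndarray | None = None
    lower_surface: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("ChoroidMask.mask must be 3D")
        for name in ("upper_surface", "lower_surface"):
            s = getattr(self, name)
            if s is not None:
                s = np.asarray(s, dtype=float)
                if s.shape != self.enface_shape:
                    raise ValueError(f"{name} shape {s.shape} != en-face shape {self.enface_shape}")
                setattr(self, name, s)
        if self.upper_surface is not None and self.lower_surface is not None:
            if np.any(self.upper_surface > self.lower_surface):
                raise ValueError("upper_surface must lie at or above lower_surface everywhere")

    @property
    def enface_shape(self) -> tuple[int, int]:
        nx, _, nz = self.mask.shape
        return nx, nz

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def cvolume_total(self) -> float:
        """Total choroidal volume: voxel count x voxel volume (mm^3)."""
        return self.voxel_count * self.spacing.voxel_volume

    @classmethod
    def from_surfaces(
        cls,
        upper: np.ndarray,
        lower: np.ndarray,
        depth: int,
        spacing: VoxelSpacing,
    ) -> "ChoroidMask":
        """Rasterize the half-open depth interval [upper, lower) into a mask."""
        upper = np.asarray(upper, dtype=float)
        lower = np.asarray(lower, dtype=float)
        y = np.arange(depth, dtype=float)
        # broadcast: (x, 1, z) vs (1, depth, 1)
        mask = (y[None, :, None] >= upper[:, None, :]) & (y[None, :, None] < lower[:, None, :])
        return cls(mask=mask, spacing=spacing, upper_surface=upper, lower_surface=lower)

    def as_grid(self) -> VoxelGrid:
        return VoxelGrid(self.mask, self.spacing)


def smooth_cs_border(lower_surface: np.ndarray, smoothing: float, depth_range: tuple[float, float] | None = None) -> np.ndarray:
    """Smooth an en-face C/S-border depth map with a cubic smoothing spline.

    The spline is fitted separably: once along every x-profile and once along
    every z-profile, and the two passes are averaged.  ``smoothing`` is the
    roughness-penalty weight (``lam`` of a cubic smoothing spline); 0 returns
    the input unchanged.  The result is clamped to ``depth_range`` if given.
    """
    if smoothing < 0:
        raise ValueError(f"smoothing must be nonnegative, got {smoothing}")
    surf = np.asarray(lower_surface, dtype=float)
    if not np.all(np.isfinite(surf)):
        raise ValueError("lower_surface must be finite everywhere")
    if smoothing == 0:
        return surf.copy()

    def _pass(arr: np.ndarray, axis: int) -> np.ndarray:
        arr = np.moveaxis(arr, axis, -1)
        n = arr.shape[-1]
        out = np.empty_like(arr)
        t = np.arange(n, dtype=float)
        if n < 4:  # too short for a cubic spline; leave unchanged
            out[...] = arr
        else:
            for idx in np.ndindex(arr.shape[:-1]):
                spl = make_smoothing_spline(t, arr[idx], lam=smoothing)
                out[idx] = spl(t)
        return np.moveaxis(out, -1, axis)

    smoothed = 0.5 * (_pass(surf, 0) + _pass(surf, 1))
    if depth_range is not None:
        smoothed = np.clip(smoothed, depth_range[0], depth_range[1])
    return smoothed


def compute_cvolume(mask: ChoroidMask, roi, region: int) -> float:
    """Choroidal volume (mm^3) of one ROI region: voxel count x dx*dy*dz."""
    labels = roi.labels
    if labels.shape != mask.enface_shape:
        raise ValueError(f"ROI shape {labels.shape} != mask en-face shape {mask.enface_shape}")
    if not roi.has_region(region):
        raise KeyError(f"unknown region id: {region}")
    sel = roi.region_mask(region)  # (x, z) en-face selector
    count = int(mask.mask.sum(axis=1)[sel].sum())
    return count * mask.spacing.voxel_volume


def compute_sfct(mask: ChoroidMask, fovea_xz: tuple[int, int], median3: bool = False) -> float:
    """Subfoveal choroidal thickness (mm): (lower - upper) x dy at the fovea.

    With ``median3`` the value is the median over the 3x3 en-face
    neighbourhood of the fovea (off by default).
    """
    fx, fz = int(fovea_xz[0]), int(fovea_xz[1])
    nx, nz = mask.enface_shape
    if not (0 <= fx < nx and 0 <= fz < nz):
        raise ValueError(f"fovea coordinate {fovea_xz} outside en-face bounds {(nx, nz)}")
    if mask.upper_surface is None or mask.lower_surface is None:
        raise ValueError(
            "boundary surfaces undefined at the fovea; derive them from the mask "
            "(contiguous run length of the A-scan column) or supply surfaces"
        )
    if median3:
        xs = slice(max(fx - 1, 0), min(fx + 2, nx))
        zs = slice(max(fz - 1, 0), min(fz + 2, nz))
        thickness = float(np.median(mask.lower_surface[xs, zs] - mask.upper_surface[xs, zs]))
    else:
        thickness = float(mask.lower_surface[fx, fz] - mask.upper_surface[fx, fz])
    return thickness * mask.spacing.dy


def sfct_from_mask(mask: ChoroidMask, fovea_xz: tuple[int, int]) -> float:
    """Fallback SFCT: longest contiguous mask run in the foveal A-scan, x dy."""
    fx, fz = int(fovea_xz[0]), int(fovea_xz[1])
    column = mask.mask[fx, :, fz]
    best = run = 0
    for v in column:
        run = run + 1 if v else 0
        best = max(best, run)
    return best * mask.spacing.dy
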