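"""Vessel volume / surface / line models.

* volume model: the binarized vessel set (input).
* surface model: vessel voxels exposed to background across any of their six
  faces; exposure across the scan border does not count.
* line model: per-slice 2D intensity maxima of the enhancement response,
  detected with a prominence criterion on every fixed-x (y, z) slice and
  every fixed-z (x, y) slice, then OR-combined and intersected with the
  volume model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import VoxelGrid

__all__ = [
    "VesselModelSet",
    "build_surface_model",
    "find_slice_maxima",
    "build_line_model",
    "build_models",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)  # in-plane 8-connectivity


@dataclass
class VesselModelSet:
    """The three binary model volumes derived from one scan."""

    volume_model: VoxelGrid
    surface_model: VoxelGrid
    line_model: VoxelGrid
    params_provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shape = self.volume_model.shape
        for name in ("surface_model", "line_model"):
            g = getattr(self, name)
            if g.shape != shape:
                raise ValueError(f"{name} shape {g.shape} != volume model shape {shape}")

    @property
    def counts(self) -> dict[str, int]:
        return {
            "volume": int(self.volume_model.data.sum()),
            "surface": int(self.surface_model.data.sum()),
            "line": int(self.line_model.data.sum()),
        }


def build_surface_model(volume_model: np.ndarray) -> np.ndarray:
    """Mark foreground voxels with a background 6-neighbour inside the scan.

    A voxel whose only background exposure lies beyond the scan border is
    not a surface voxel.
    """
    fg = np.asarray(volume_model, dtype=bool)
    if fg.ndim != 3:
        raise ValueError("volume model must be 3D")
    surface = np.zeros_like(fg)
    for axis in range(3):
        lo = tuple(slice(0, -1) if i == axis else slice(None) for i in range(3))
        hi = tuple(slice(1, None) if i == axis else slice(None) for i in range(3))
        surface[lo] |= fg[lo] & ~fg[hi]
        surface[hi] |= fg[hi] & ~fg[lo]
    return surface


def _plateau_point(coords: np.ndarray) -> tuple[int, int]:
    """Centroid of a plateau's pixel coordinates, rounding half toward the
    smaller index (one deterministic point per plateau)."""
    m = coords.mean(axis=0)
    return tuple(int(np.ceil(c - 0.5)) for c in m)  # type: ignore[return-value]


def find_slice_maxima(slice2d: np.ndarray, prominence: float) -> set[tuple[int, int]]:
    """Prominence-filtered local maxima of a 2D image.

    A regional-maximum plateau of height ``v`` is reported iff no path of
    pixels with value >= ``v - prominence`` (8-connected) leads to a pixel
    strictly higher than ``v``; a constant image has no maxima.  Equal-height
    maxima that are mutually reachable by such a path belong to the same
    tolerance basin and are merged into a single reported point (this is how
    quantized ridge crests collapse to one maximum).  Each reported point is
    the centroid pixel of its (merged) plateau, ties rounded toward the
    smaller index.
    """
    if prominence < 0:
        raise ValueError("prominence must be nonnegative")
    img = np.asarray(slice2d, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D slice")
    if img.size == 0 or img.min() == img.max():
        return set()

    # candidate plateaus: connected sets of pixels with no strictly-higher
    # 8-neighbour.  A flat region whose rim touches higher pixels leaves its
    # interior marked too; such spurious plateaus are eliminated by the flood
    # check below (an equal-valued path to a higher pixel always exists), and
    # global-minimum plateaus can never be true maxima, so they are skipped.
    footprint = np.ones((3, 3))
    neigh_max = ndimage.maximum_filter(img, footprint=footprint, mode="constant", cval=-np.inf)
    candidate_px = img >= neigh_max
    plateau_labels, n_plateaus = ndimage.label(candidate_px, structure=_STRUCT8)
    if n_plateaus == 0:
        return set()
    plateau_values = ndimage.maximum(img, plateau_labels, index=np.arange(1, n_plateaus + 1))

    points: set[tuple[int, int]] = set()
    # group plateaus by height so one connected-component pass serves all
    # plateaus of that height
    vmin = float(img.min())
    by_value: dict[float, list[int]] = {}
    for idx in np.argsort(plateau_values)[::-1]:
        v = float(plateau_values[idx])
        if v > vmin:
            by_value.setdefault(v, []).append(idx + 1)

    for v, labels_at_v in by_value.items():
        # tolerance basins: connected components of {img >= v - prominence}
        comp, _ = ndimage.label(img >= v - prominence, structure=_STRUCT8)
        higher = img > v
        reachable_higher_comp = set(np.unique(comp[higher]).tolist()) if higher.any() else set()
        merged: dict[int, list[np.ndarray]] = {}
        for lab in labels_at_v:
            coords = np.argwhere(plateau_labels == lab)
            cid = int(comp[coords[0, 0], coords[0, 1]])
            if cid in reachable_higher_comp:
                continue  # absorbed by a higher maximum within tolerance
            merged.setdefault(cid, []).append(coords)
        for groups in merged.values():
            points.add(_plateau_point(np.vstack(groups)))
    return points


def build_line_model(response: VoxelGrid, volume_model: np.ndarray, prominence: float = 10.0) -> np.ndarray:
    """Line model: slice-wise maxima of the masked response along two axes.

    ``find_slice_maxima`` runs on every fixed-x slice and every fixed-z
    slice of ``response`` with values outside ``volume_model`` zeroed; the
    two passes are OR-combined and intersected with the volume model.
    """
    vm = np.asarray(volume_model, dtype=bool)
    if response.shape != vm.shape:
        raise ValueError(f"response shape {response.shape} != volume model shape {vm.shape}")
    masked = np.where(vm, response.data, 0).astype(np.float64)
    line = np.zeros(vm.shape, dtype=bool)
    nx, _, nz = vm.shape
    for x in range(nx):
        for (y, z) in find_slice_maxima(masked[x], prominence):
            line[x, y, z] = True
    for z in range(nz):
        for (x, y) in find_slice_maxima(masked[:, :, z], prominence):
            line[x, y, z] = True
    return line & vm


def build_models(
    response: VoxelGrid,
    binary_vessels: VoxelGrid,
    prominence: float = 10.0,
    provenance: dict | None = None,
) -> VesselModelSet:
    """Assemble the three models from the response and the binarized vessels."""
    vm = np.asarray(binary_vessels.data, dtype=bool)
    surface = build_surface_model(vm)
    line = build_line_model(response, vm, prominence)
    prov = {"prominence": prominence}
    if provenance:
        prov.update(provenance)
    spacing = binary_vessels.spacing
    return VesselModelSet(
        volume_model=VoxelGrid(vm, spacing),
        surface_model=VoxelGrid(surface, spacing),
        line_model=VoxelGrid(line, spacing),
        params_provenance=prov,
    )
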