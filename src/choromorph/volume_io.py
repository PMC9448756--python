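"""Voxel volume I/O and the coordinate convention used across the package.

Arrays are indexed ``(x, y, z)`` where

* ``x`` is the fast-scan (horizontal, en-face) axis,
* ``y`` is the depth (A-scan) axis,
* ``z`` is the slow-scan (B-scan stacking) axis.

The en-face plane is ``(x, z)``.  A "slice along the x-axis" is the
fixed-``x`` plane ``(y, z)``; a "slice along the z-axis" is the fixed-``z``
plane ``(x, y)``.  Multi-page TIFF stacks store one slow-scan slice per page
(page ``z`` holds a ``(y, x)``-shaped image), with spacing and dtype recorded
in a YAML sidecar so that reads invert writes exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

log = logging.getLogger(__name__)

__all__ = [
    "VoxelSpacing",
    "VoxelGrid",
    "DEFAULT_SPACING",
    "PAPER_SPACING",
    "read_volume",
    "write_volume",
]

_SUPPORTED_DTYPES = {
    "uint8": np.uint8,
    "uint16": np.uint16,
    "float32": np.float32,
    "float64": np.float64,
}


@dataclass(frozen=True)
class VoxelSpacing:
    """Physical voxel pitch in millimetres along (x, y, z)."""

    dx: float
    dy: float
    dz: float

    def __post_init__(self) -> None:
        for name in ("dx", "dy", "dz"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"VoxelSpacing.{name} must be strictly positive, got {v!r}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3 (dx * dy * dz)."""
        return self.dx * self.dy * self.dz

    def scaled(self, factor: float) -> "VoxelSpacing":
        return VoxelSpacing(self.dx * factor, self.dy * factor, self.dz * factor)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dx, self.dy, self.dz)


#: Exact spacing of a 500 x 256 x 500 voxel scan covering 6 x 3 x 6 mm.
DEFAULT_SPACING = VoxelSpacing(6.0 / 500.0, 3.0 / 256.0, 6.0 / 500.0)

#: Spacing with the depth pitch rounded to 11.72e-3 mm, the constant used in
#: the published scaling formulas.  Used by default for morphometric scaling
#: so that worked numbers reproduce printed arithmetic.
PAPER_SPACING = VoxelSpacing(12e-3, 11.72e-3, 12e-3)


@dataclass
class VoxelGrid:
    """A 3D scalar volume with physical spacing.

    ``data`` is indexed ``(x, y, z)``; see the module docstring for the axis
    convention.  Derived volumes (masks, vessel models) must share ``shape``
    and ``spacing`` with their parent grid.
    """

    data: np.ndarray
    spacing: VoxelSpacing

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid requires a 3D array, got ndim={self.data.ndim}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def dtype_tag(self) -> str:
        return str(self.data.dtype)

    @property
    def enface_shape(self) -> tuple[int, int]:
        nx, _, nz = self.data.shape
        return nx, nz

    def astype(self, dtype) -> "VoxelGrid":
        return VoxelGrid(self.data.astype(dtype), self.spacing)

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and self.spacing == other.spacing


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_volume(grid: VoxelGrid, path) -> None:
    """Write ``grid`` as a multi-page TIFF plus a YAML sidecar.

    Pages are slow-scan (z) slices in increasing z; each page is a (y, x)
    image.  ``read_volume`` inverts this exactly for every supported dtype.
    Boolean grids are stored as uint8 {0, 255} with ``mask: true`` recorded
    in the sidecar.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = grid.data
    is_mask = data.dtype == bool
    if is_mask:
        data = np.where(data, np.uint8(255), np.uint8(0))
    if str(data.dtype) not in _SUPPORTED_DTYPES:
        raise TypeError(f"unsupported dtype for TIFF export: {data.dtype}")
    pages = np.ascontiguousarray(data.transpose(2, 1, 0))  # (z, y, x)
    tifffile.imwrite(path, pages)
    meta = {
        "shape": list(grid.data.shape),
        "dtype": str(data.dtype),
        "mask": bool(is_mask),
        "spacing_mm": [grid.spacing.dx, grid.spacing.dy, grid.spacing.dz],
    }
    _sidecar_path(path).write_text(yaml.safe_dump(meta, sort_keys=True))


def read_volume(path, spacing_override: VoxelSpacing | None = None, as_mask: bool = False) -> VoxelGrid:
    """Read a multi-page TIFF (or raw binary + sidecar) into a VoxelGrid.

    Parameters
    ----------
    path:
        TIFF stack written by :func:`write_volume`, or a raw little-endian
        binary with a mandatory YAML sidecar giving ``shape``, ``dtype`` and
        ``spacing_mm``.
    spacing_override:
        If given, replaces any spacing found in the sidecar.
    as_mask:
        Force interpretation as a binary mask (nonzero -> True).  Volumes
        written from boolean grids set ``mask: true`` in their sidecar and
        round-trip automatically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}

    if path.suffix.lower() in {".tif", ".tiff"}:
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        data = pages.transpose(2, 1, 0)  # back to (x, y, z)
        if "shape" in meta and tuple(meta["shape"]) != data.shape:
            raise ValueError(
                f"sidecar field 'shape' {tuple(meta['shape'])} does not match TIFF data shape {data.shape}"
            )
    else:  # raw binary; sidecar is mandatory
        for field in ("shape", "dtype"):
            if field not in meta:
                raise ValueError(f"raw volume sidecar is missing required field {field!r}: {sidecar}")
        if meta["dtype"] not in _SUPPORTED_DTYPES:
            raise TypeError(f"sidecar field 'dtype' unsupported: {meta['dtype']!r}")
        shape = tuple(int(s) for s in meta["shape"])
        data = np.fromfile(path, dtype=_SUPPORTED_DTYPES[meta["dtype"]])
        if data.size != int(np.prod(shape)):
            raise ValueError(
                f"sidecar field 'shape' {shape} implies {int(np.prod(shape))} voxels, file holds {data.size}"
            )
        data = data.reshape(shape)

    if spacing_override is not None:
        spacing = spacing_override
    elif "spacing_mm" in meta:
        spacing = VoxelSpacing(*[float(v) for v in meta["spacing_mm"]])
    else:
        spacing = DEFAULT_SPACING
        log.warning("no spacing metadata for %s; assuming default %s", path, spacing)

    if as_mask or meta.get("mask", False):
        data = data > 0
    grid = VoxelGrid(data, spacing)
    log.info("read %s: shape=%s dtype=%s spacing=%s", path, grid.shape, grid.dtype_tag, spacing)
    return grid
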