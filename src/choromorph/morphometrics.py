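"""The eleven morphometric parameters of one eye, per ROI region.

All parameters derive from four voxel counts (choroid, vessel volume model,
vessel surface model, vessel line model), one region area and the voxel
volume ``v = dx*dy*dz``:

    CVolume  = N_cho  * v            [mm^3]
    VVolume  = N_ves  * v            [mm^3]
    VSurface = N_surf * v^(2/3)      [mm^2]
    VLI      = N_line * v^(1/3)      [mm]
    MCT      = CVolume / area        [mm]
    CVI      = VVolume / CVolume     [-]
    VLDI     = VLI / VVolume         [mm^-2]
    VLS      = VLI / (CVolume - VVolume)   [mm^-2]
    SV       = VSurface / VVolume    [mm^-1]
    VDI      = sqrt(VVolume / VLI)   [mm]  (tabulated as um, x1000)

plus SFCT (whole-eye, from the boundary surfaces at the fovea).  Undefined
ratios (zero denominators) are reported as missing values with a reason
code — never as numeric zeros.  Pooled rows (parafovea, total) are always
recomputed from pooled voxel counts, not averaged from per-region ratios,
so extensive parameters stay exactly additive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .choroid_mask import ChoroidMask
from .roi_grid import PARAFOVEA_REGIONS, REGION_NAMES, RoiGrid
from .vessel_models import VesselModelSet
from .volume_io import VoxelSpacing

__all__ = ["MorphometricRecord", "count_in_region", "compute_parameters", "summarize_eye", "PARAMETER_UNITS"]

PARAMETER_UNITS = {
    "SFCT": "mm",
    "CVolume": "mm^3",
    "MCT": "mm",
    "VVolume": "mm^3",
    "VSurface": "mm^2",
    "VLI": "mm",
    "CVI": "",
    "VLDI": "mm^-2",
    "VLS_ratio": "mm^-2",
    "SV_ratio": "mm^-1",
    "VDI": "mm",
    "VDI_um": "um",
}

#: Table row order for wide per-eye output.
PARAMETER_ORDER = [
    "CVolume", "MCT", "VVolume", "VSurface", "VLI",
    "VLDI", "VLS_ratio", "VDI_um", "SV_ratio", "CVI", "SFCT",
]


@dataclass
class MorphometricRecord:
    """Voxel counts plus derived parameters for one region of one eye.

    Parameters are recomputed on access from the stored counts, which makes
    pooling (``+``) exact: counts and areas add, ratios rebuild.
    """

    region: str
    n_choroid: int
    n_vessel: int
    n_surface: int
    n_line: int
    area_mm2: float
    spacing: VoxelSpacing
    sfct_mm: float | None = None
    undefined: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_vessel > self.n_choroid:
            raise ValueError("vessel voxel count exceeds choroid voxel count")
        for name in ("n_choroid", "n_vessel", "n_surface", "n_line"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    # -- extensive ---------------------------------------------------------
    @property
    def voxel_volume(self) -> float:
        return self.spacing.voxel_volume

    @property
    def cvolume(self) -> float:
        return self.n_choroid * self.voxel_volume

    @property
    def vvolume(self) -> float:
        return self.n_vessel * self.voxel_volume

    @property
    def vsurface(self) -> float:
        return self.n_surface * self.voxel_volume ** (2.0 / 3.0)

    @property
    def vli(self) -> float:
        return self.n_line * self.voxel_volume ** (1.0 / 3.0)

    # -- intensive ---------------------------------------------------------
    def _intensive(self, name: str, num: float, den: float, reason: str) -> float | None:
        if self.n_choroid == 0:
            self.undefined[name] = "CVolume is zero"
            return None
        if den == 0:
            self.undefined[name] = reason
            return None
        return num / den

    @property
    def mct(self) -> float | None:
        return self._intensive("MCT", self.cvolume, self.area_mm2, "region area is zero")

    @property
    def cvi(self) -> float | None:
        return self._intensive("CVI", self.vvolume, self.cvolume, "CVolume is zero")

    @property
    def vldi(self) -> float | None:
        return self._intensive("VLDI", self.vli, self.vvolume, "VVolume is zero")

    @property
    def vls_ratio(self) -> float | None:
        return self._intensive("VLS_ratio", self.vli, self.cvolume - self.vvolume, "stromal volume is zero")

    @property
    def sv_ratio(self) -> float | None:
        return self._intensive("SV_ratio", self.vsurface, self.vvolume, "VVolume is zero")

    @property
    def vdi(self) -> float | None:
        ratio = self._intensive("VDI", self.vvolume, self.vli, "VLI is zero")
        if ratio is None:
            return None
        if self.n_vessel == 0:
            self.undefined["VDI"] = "VVolume is zero"
            return None
        return math.sqrt(ratio)

    @property
    def vdi_um(self) -> float | None:
        vdi = self.vdi
        return None if vdi is None else vdi * 1000.0

    def __add__(self, other: "MorphometricRecord") -> "MorphometricRecord":
        if self.spacing != other.spacing:
            raise ValueError("cannot pool records with different spacing")
        return MorphometricRecord(
            region=f"{self.region}+{other.region}",
            n_choroid=self.n_choroid + other.n_choroid,
            n_vessel=self.n_vessel + other.n_vessel,
            n_surface=self.n_surface + other.n_surface,
            n_line=self.n_line + other.n_line,
            area_mm2=self.area_mm2 + other.area_mm2,
            spacing=self.spacing,
            sfct_mm=self.sfct_mm if self.sfct_mm is not None else other.sfct_mm,
        )

    def as_dict(self) -> dict:
        d = {
            "region": self.region,
            "CVolume": self.cvolume,
            "MCT": self.mct,
            "VVolume": self.vvolume,
            "VSurface": self.vsurface,
            "VLI": self.vli,
            "VLDI": self.vldi,
            "VLS_ratio": self.vls_ratio,
            "VDI_um": self.vdi_um,
            "SV_ratio": self.sv_ratio,
            "CVI": self.cvi,
            "SFCT": self.sfct_mm,
            "area_mm2": self.area_mm2,
        }
        d["undefined_reasons"] = dict(self.undefined)
        return d


def count_in_region(model: np.ndarray, roi: RoiGrid, region: int) -> int:
    """Number of True voxels whose en-face (x, z) position lies in a region."""
    model = np.asarray(model)
    nx, _, nz = model.shape
    if roi.labels.shape != (nx, nz):
        raise ValueError(f"ROI shape {roi.labels.shape} != en-face shape {(nx, nz)}")
    sel = roi.region_mask(region)
    return int(model.sum(axis=1)[sel].sum())


def compute_parameters(
    mask: ChoroidMask,
    models: VesselModelSet,
    roi: RoiGrid,
    region: int,
    sfct_mm: float | None = None,
    scaling_spacing: VoxelSpacing | None = None,
) -> MorphometricRecord:
    """All parameters of one ROI region from the mask and the three models.

    ``scaling_spacing`` substitutes the spacing constants used in the
    scaling formulas (e.g. the published rounded depth pitch) without
    touching the voxel counts; default is the mask's own spacing.
    """
    for name, g in (("volume", models.volume_model), ("surface", models.surface_model), ("line", models.line_model)):
        if g.data.shape != mask.mask.shape:
            raise ValueError(f"{name} model shape {g.data.shape} != mask shape {mask.mask.shape}")
    spacing = scaling_spacing or mask.spacing
    return MorphometricRecord(
        region=REGION_NAMES.get(region, str(region)),
        n_choroid=count_in_region(mask.mask, roi, region),
        n_vessel=count_in_region(models.volume_model.data, roi, region),
        n_surface=count_in_region(models.surface_model.data, roi, region),
        n_line=count_in_region(models.line_model.data, roi, region),
        area_mm2=roi.areas_mm2[region],
        spacing=spacing,
        sfct_mm=sfct_mm,
    )


def summarize_eye(records: dict[int, MorphometricRecord], include_quadrants: bool = False) -> pd.DataFrame:
    """Center / parafovea / total table from per-region records.

    Pooled rows are built from pooled voxel counts; intensive parameters are
    therefore self-consistent with the pooled extensive ones, never averages
    of per-region ratios.
    """
    missing = [r for r in (1,) + PARAFOVEA_REGIONS if r not in records]
    if missing:
        raise KeyError(f"missing region records: {missing}")
    center = records[1]
    parafovea = records[PARAFOVEA_REGIONS[0]]
    for r in PARAFOVEA_REGIONS[1:]:
        parafovea = parafovea + records[r]
    parafovea.region = "parafovea"
    total = center + parafovea
    total.region = "total"
    rows = [center, parafovea, total]
    if include_quadrants:
        rows = [records[r] for r in PARAFOVEA_REGIONS] + rows
    return pd.DataFrame([r.as_dict() for r in rows]).set_index("region")
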