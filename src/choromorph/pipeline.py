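"""End-to-end orchestration: volume + choroid mask -> models -> parameters.

`analyze_volume` is the in-memory chain used by the CLI, the tests and the
acceptance harness; `run_pipeline` wraps it with file I/O, config handling
and a provenance sidecar.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .choroid_mask import ChoroidMask, compute_sfct
from .morphometrics import compute_parameters, summarize_eye
from .roi_grid import CIRCLE_REGIONS, build_roi
from .vessel_models import VesselModelSet, build_models
from .vesselness import VesselnessParams, binarize_vessels, hessian_vesselness, invert_and_normalize, to_8bit
from .volume_io import VoxelGrid, VoxelSpacing, read_volume, write_volume

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serializable run settings; config + inputs determine outputs."""

    spacing: VoxelSpacing | None = None  # None: take from input metadata
    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    prominence: float = 10.0
    low_pct: float = 0.5
    high_pct: float = 99.5
    fovea_xz: tuple[int, int] | None = None  # None: en-face centre
    laterality: str = "right"
    seed: int = 0

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spacing"] = None if self.spacing is None else list(self.spacing.as_tuple())
        d["vesselness"] = dataclasses.asdict(self.vesselness)
        d["vesselness"]["scales"] = list(self.vesselness.scales)
        d["fovea_xz"] = None if self.fovea_xz is None else list(self.fovea_xz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("spacing") is not None:
            d["spacing"] = VoxelSpacing(*d["spacing"])
        if "vesselness" in d and isinstance(d["vesselness"], dict):
            v = dict(d["vesselness"])
            if "scales" in v:
                v["scales"] = tuple(v["scales"])
            d["vesselness"] = VesselnessParams(**v)
        if d.get("fovea_xz") is not None:
            d["fovea_xz"] = tuple(int(v) for v in d["fovea_xz"])
        return cls(**d)


@dataclass
class AnalysisResult:
    models: VesselModelSet
    roi: "object"
    response_8bit: VoxelGrid
    table: pd.DataFrame


def analyze_volume(grid: VoxelGrid, mask: ChoroidMask, config: RunConfig) -> AnalysisResult:
    """Run enhancement, model construction, ROI gridding and measurement."""
    normalized = invert_and_normalize(grid, config.low_pct, config.high_pct)
    response = hessian_vesselness(normalized, config.vesselness)
    response8 = to_8bit(response)
    binary = binarize_vessels(response8, mask, config.vesselness.threshold_8bit)
    models = build_models(
        response8,
        binary,
        prominence=config.prominence,
        provenance={"vesselness": dataclasses.asdict(config.vesselness)},
    )

    fovea = config.fovea_xz or (grid.shape[0] // 2, grid.shape[2] // 2)
    roi = build_roi(grid.enface_shape, grid.spacing, fovea, config.laterality)
    sfct = None
    if mask.upper_surface is not None and mask.lower_surface is not None:
        sfct = compute_sfct(mask, fovea)
    records = {r: compute_parameters(mask, models, roi, r, sfct_mm=sfct if r == 1 else None) for r in CIRCLE_REGIONS}
    table = summarize_eye(records, include_quadrants=True)
    return AnalysisResult(models=models, roi=roi, response_8bit=response8, table=table)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, volume_path, mask_path, out_dir) -> Path:
    """File-level pipeline: read inputs, analyze, write models/CSV/provenance."""
    volume_path, mask_path, out_dir = Path(volume_path), Path(mask_path), Path(out_dir)
    for p in (volume_path, mask_path):
        if not p.exists():
            raise FileNotFoundError(f"input not found: {p}")
    out_dir.mkdir(parents=True, exist_ok=True)

    grid = read_volume(volume_path, spacing_override=config.spacing)
    mask_grid = read_volume(mask_path, spacing_override=config.spacing or grid.spacing, as_mask=True)
    if mask_grid.shape != grid.shape:
        raise ValueError(f"mask shape {mask_grid.shape} != volume shape {grid.shape}")
    mask = ChoroidMask(mask=mask_grid.data, spacing=grid.spacing)

    result = analyze_volume(grid, mask, config)

    write_volume(result.models.volume_model, out_dir / "vessel_volume_model.tif")
    write_volume(result.models.surface_model, out_dir / "vessel_surface_model.tif")
    write_volume(result.models.line_model, out_dir / "vessel_line_model.tif")
    result.table.to_csv(out_dir / "parameters_wide.csv")
    tidy = (
        result.table.drop(columns=["undefined_reasons"])
        .reset_index()
        .melt(id_vars="region", var_name="parameter", value_name="value")
        .sort_values(["region", "parameter"], kind="stable")
    )
    tidy.to_csv(out_dir / "parameters_tidy.csv", index=False)

    provenance = {
        "software_version": __version__,
        "config": config.as_dict(),
        "inputs": {
            str(volume_path): _sha256(volume_path),
            str(mask_path): _sha256(mask_path),
        },
        "model_voxel_counts": result.models.counts,
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    log.info("pipeline outputs written to %s", out_dir)
    return out_dir
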