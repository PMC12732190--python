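"""Run configuration: YAML plate/assay description for the CLI.

A run config declares the physical plate, pixel-scale calibration, row
roles (which row is the PHA-P positive control, which the PBS negative
control), thresholds, and ELISA back-calculation constants.  Roles live in
config, never inferred from image content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .geometry import PixelScale, PlateGeometry, calibrate_scale

__all__ = ["RowRole", "ElisaConfig", "RunConfig", "load_config"]

_ROLES = {"positive_control", "sample", "negative_control"}


@dataclass(frozen=True)
class RowRole:
    role: str
    sample_id: str
    expected_last_positive: int | None = None
    start_conc_ng_per_ul: float | None = None


@dataclass(frozen=True)
class ElisaConfig:
    well_volume_ul: float = 100.0
    extract_mg_powder_per_ul: float = 0.1
    lloq_ng: float = 15.0


@dataclass
class RunConfig:
    geometry: PlateGeometry
    scale: PixelScale
    anchor_px: tuple[float, float]
    roles: dict[int, RowRole]
    rotation_deg: float = 0.0
    crop_box: tuple[int, int, int, int] | None = None
    threshold_gray: int = 235
    sigma_multiplier: float = 3.0
    theta_ng: float = 200.0
    dilution_factor: float = 2.0
    exposure_offset: float = 0.0
    elisa: ElisaConfig = field(default_factory=ElisaConfig)

    def __post_init__(self) -> None:
        bad = {r: v.role for r, v in self.roles.items() if v.role not in _ROLES}
        if bad:
            raise ConfigError(f"unknown row roles: {bad}; must be one of {sorted(_ROLES)}")
        n_neg = sum(1 for v in self.roles.values() if v.role == "negative_control")
        if n_neg != 1:
            raise ConfigError(
                f"exactly one negative-control row is required, found {n_neg}"
            )


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a YAML mapping")
    try:
        plate = raw.get("plate", {})
        geometry = PlateGeometry(
            n_rows=int(plate.get("n_rows", 8)),
            n_cols=int(plate.get("n_cols", 12)),
            well_bottom_diameter_mm=float(plate.get("well_bottom_diameter_mm", 6.4)),
            well_pitch_mm=float(plate.get("well_pitch_mm", 9.0)),
            roi_fraction=float(plate.get("roi_fraction", 0.95)),
        )
        scale_block = raw.get("scale", {})
        if "mm_per_px" in scale_block:
            scale = PixelScale(float(scale_block["mm_per_px"]))
        elif "well_edge_to_edge_px" in scale_block:
            scale = calibrate_scale(
                float(scale_block["well_edge_to_edge_px"]),
                geometry.well_bottom_diameter_mm,
            )
        else:
            raise ConfigError(
                "scale block needs either mm_per_px or well_edge_to_edge_px"
            )
        anchor = plate.get("anchor_px")
        if anchor is None or len(anchor) != 2:
            raise ConfigError("plate.anchor_px: [x, y] of the A1 well center is required")
        crop = plate.get("crop_box")
        roles: dict[int, RowRole] = {}
        for key, block in (raw.get("rows") or {}).items():
            roles[int(key)] = RowRole(
                role=str(block.get("role", "")),
                sample_id=str(block.get("sample_id", f"row{key}")),
                expected_last_positive=(
                    int(block["expected_last_positive"])
                    if block.get("expected_last_positive") is not None
                    else None
                ),
                start_conc_ng_per_ul=(
                    float(block["start_conc_ng_per_ul"])
                    if block.get("start_conc_ng_per_ul") is not None
                    else None
                ),
            )
        if not roles:
            raise ConfigError("config must declare row roles under `rows:`")
        elisa_block = raw.get("elisa", {})
        return RunConfig(
            geometry=geometry,
            scale=scale,
            anchor_px=(float(anchor[0]), float(anchor[1])),
            roles=roles,
            rotation_deg=float(plate.get("rotation_deg", 0.0)),
            crop_box=tuple(int(v) for v in crop) if crop else None,
            threshold_gray=int(raw.get("threshold_gray", 235)),
            sigma_multiplier=float(raw.get("sigma_multiplier", 3.0)),
            theta_ng=float(raw.get("theta_ng", 200.0)),
            dilution_factor=float(raw.get("dilution_factor", 2.0)),
            exposure_offset=float(raw.get("exposure_offset", 0.0)),
            elisa=ElisaConfig(
                well_volume_ul=float(elisa_block.get("well_volume_ul", 100.0)),
                extract_mg_powder_per_ul=float(
                    elisa_block.get("extract_mg_powder_per_ul", 0.1)
                ),
                lloq_ng=float(elisa_block.get("lloq_ng", 15.0)),
            ),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"{path}: invalid configuration ({exc})") from exc
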