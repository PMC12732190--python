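"""Workflow orchestration: measurements -> endpoint calls -> reports.

Ties the measurement, endpoint and quantitation stages together the way a
run proceeds at the bench: measure every row of each plate photograph,
merge multi-plate series by well index, establish the negative-control
threshold from the designated PBS row of the same run, call endpoints and
titers per sample row, and QC the positive-control row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .endpoint import (
    EndpointCall,
    NegativeControlStats,
    QcResult,
    call_endpoint,
    negative_stats,
    qc_positive_control,
)
from .errors import ConfigError
from .geometry import RoiGrid
from .measure import PlateImage, measure_plate, measurements_to_frame
from .quant import DilutionSeries, pha_conc_hemagglutination
from .synth import PlateRender

log = logging.getLogger("hemaquant")

__all__ = ["RowResult", "RunResult", "analyze_areas", "analyze_images", "analyze_rendered"]


@dataclass(frozen=True)
class RowResult:
    """Endpoint call (and QC outcome, for the positive control) of one row."""

    row: int
    sample_id: str
    role: str
    areas: tuple[float, ...]
    call: EndpointCall | None  # None for the negative-control row
    qc: QcResult | None = None


@dataclass
class RunResult:
    stats: NegativeControlStats
    rows: list[RowResult]

    @property
    def qc_passed(self) -> bool:
        return all(r.qc.passed for r in self.rows if r.qc is not None)

    def row(self, row_index: int) -> RowResult:
        return next(r for r in self.rows if r.row == row_index)

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            if r.call is None:
                continue
            recs.append(
                {
                    "sample_id": r.sample_id,
                    "role": r.role,
                    "row": r.row,
                    "last_positive": r.call.last_positive,
                    "first_negative": r.call.first_negative,
                    "hau": r.call.hau_display,
                    "artifact_wells": ";".join(str(w) for w in r.call.artifact_wells),
                    "threshold_area_mm2": r.call.threshold_area_mm2,
                    "qc": "" if r.qc is None else ("pass" if r.qc.passed else "fail"),
                }
            )
        return pd.DataFrame.from_records(recs)


def analyze_areas(
    areas_by_row: dict[int, list[float]],
    roles: dict[int, str],
    sample_ids: dict[int, str] | None = None,
    dilution_factor: float = 2.0,
    sigma_multiplier: float = 3.0,
    qc_expected: dict[int, int] | None = None,
    qc_tolerance: int = 0,
) -> RunResult:
    """Call endpoints for every row given per-row ordered area vectors.

    Exactly one row must carry the ``negative_control`` role; its wells set
    the mean+sigma*SD threshold for this run and this run only.
    """
    neg_rows = [r for r, role in roles.items() if role == "negative_control"]
    if len(neg_rows) != 1:
        raise ConfigError(
            f"exactly one negative-control row is required per run, found {len(neg_rows)}"
        )
    missing = set(areas_by_row) - set(roles)
    if missing:
        raise ConfigError(f"rows without a declared role: {sorted(missing)}")
    stats = negative_stats(areas_by_row[neg_rows[0]], sigma_multiplier=sigma_multiplier)
    sample_ids = sample_ids or {}
    qc_expected = qc_expected or {}
    results: list[RowResult] = []
    for row in sorted(areas_by_row):
        role = roles[row]
        sid = sample_ids.get(row, f"row{row}")
        areas = tuple(float(a) for a in areas_by_row[row])
        if role == "negative_control":
            results.append(RowResult(row, sid, role, areas, call=None))
            continue
        call = call_endpoint(areas, stats, dilution_factor=dilution_factor)
        qc = None
        if role == "positive_control" and row in qc_expected:
            qc = qc_positive_control(call, qc_expected[row], qc_tolerance)
        log.info(
            "row %d (%s): threshold %.3f mm2, last_positive %s, HAU %s",
            row,
            sid,
            stats.threshold_area_mm2,
            call.last_positive,
            call.hau_display,
        )
        results.append(RowResult(row, sid, role, areas, call=call, qc=qc))
    return RunResult(stats=stats, rows=results)


def _areas_from_plates(
    images: list[PlateImage], grids: list[RoiGrid], threshold_gray: int
) -> tuple[dict[int, list[float]], pd.DataFrame]:
    """Measure every plate and concatenate rows across plates by well index."""
    frames = []
    areas: dict[int, list[float]] = {}
    for p, (img, grid) in enumerate(zip(images, grids)):
        ms = measure_plate(img, grid, threshold_max=threshold_gray)
        frames.append(measurements_to_frame(ms, plate_id=f"plate_{p:03d}"))
        for row in sorted({m.row for m in ms}):
            row_ms = sorted((m for m in ms if m.row == row), key=lambda m: m.col)
            areas.setdefault(row, []).extend(m.area_mm2 for m in row_ms)
    return areas, pd.concat(frames, ignore_index=True)


def analyze_images(
    images: list[PlateImage],
    grids: list[RoiGrid],
    roles: dict[int, str],
    sample_ids: dict[int, str] | None = None,
    threshold_gray: int = 235,
    dilution_factor: float = 2.0,
    sigma_multiplier: float = 3.0,
    qc_expected: dict[int, int] | None = None,
    qc_tolerance: int = 0,
) -> tuple[RunResult, pd.DataFrame]:
    """Full imaging run: measure plates, merge, call endpoints.

    Returns the run result plus the per-well measurement table.
    """
    areas, measurements = _areas_from_plates(images, grids, threshold_gray)
    result = analyze_areas(
        areas,
        roles,
        sample_ids=sample_ids,
        dilution_factor=dilution_factor,
        sigma_multiplier=sigma_multiplier,
        qc_expected=qc_expected,
        qc_tolerance=qc_tolerance,
    )
    return result, measurements


def analyze_rendered(
    render: PlateRender,
    threshold_gray: int = 235,
    sigma_multiplier: float = 3.0,
    qc_expected: dict[int, int] | None = None,
) -> RunResult:
    """Analyze a synthetic render end-to-end using its own geometry/scale."""
    from .measure import to_grayscale_8bit

    images = [to_grayscale_8bit(img, scale=render.scale) for img in render.images]
    truth = render.truth
    roles = (
        truth[["row", "role"]].drop_duplicates().set_index("row")["role"].to_dict()
    )
    sample_ids = (
        truth[["row", "sample_id"]].drop_duplicates().set_index("row")["sample_id"].to_dict()
    )
    dilution_factor = 2.0
    result, _ = analyze_images(
        images,
        render.grids,
        roles={int(k): v for k, v in roles.items()},
        sample_ids={int(k): v for k, v in sample_ids.items()},
        threshold_gray=threshold_gray,
        dilution_factor=dilution_factor,
        sigma_multiplier=sigma_multiplier,
        qc_expected=qc_expected,
    )
    return result


def estimate_row_concentration(
    result: RunResult,
    row: int,
    series: DilutionSeries,
    theta_ng: float = 200.0,
):
    """Convenience: active-lectin mg/g for a powder-extract sample row."""
    call = result.row(row).call
    if call is None:
        raise ConfigError(f"row {row} is the negative control; no endpoint to quantify")
    return pha_conc_hemagglutination(series, call.first_negative, theta_ng=theta_ng)
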