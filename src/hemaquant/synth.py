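"""Synthetic plate-photograph renderer with known ground truth.

Renders 96-well round-bottom plate photographs the way the imaging pipeline
expects them: a white backlit background with red-toned well contents.  Each
well's phenotype is simulated from the analyte amount it holds:

* ``mat`` — broad agglutinated mat, far above the detection threshold;
* ``fuzzy_mat`` — smaller, oblong mat near the endpoint;
* ``donut`` — near-endpoint mat with a central hole;
* ``pellet`` — compact dark dot of settled cells (negative);
* ``edge_polygon`` — the high-concentration edge-effect artifact: the mat
  rolls into a few small polygons whose thresholded area is deceptively
  small (below even the pellet band), which is what the endpoint caller
  must flag and ignore.

Positivity follows a logistic in log2(amount/theta) with configurable
width; at width 0 it is a hard step at theta (amount >= theta is positive).
An illumination gradient and Gaussian sensor noise are applied per plate.
All randomness flows through one seeded generator, so renders are
bit-reproducible.

Idealizations relative to real photographs: no meniscus refraction or
specular highlights, well contents are centered up to a small jitter, and
pellet-area variation is bounded (uniform), not heavy-tailed.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from skimage.draw import polygon as _sk_polygon

from .errors import ConfigError
from .geometry import PlateGeometry, PixelScale, RoiGrid, build_roi_grid
from .quant import DilutionSeries, amount_in_well

__all__ = [
    "WellPhenotype",
    "RenderParams",
    "RowSpec",
    "PlateRender",
    "simulate_phenotype",
    "render_plate",
    "write_render",
]

WellState = Literal["mat", "edge_polygon", "fuzzy_mat", "donut", "pellet"]

# RGB tones chosen so every phenotype falls below the 235 gray threshold
# after luminance conversion while the white background stays above it.
_COLORS: dict[str, tuple[int, int, int]] = {
    "mat": (205, 105, 105),
    "fuzzy_mat": (210, 120, 120),
    "donut": (205, 105, 105),
    "pellet": (150, 30, 30),
    "edge_polygon": (195, 85, 85),
}


@dataclass(frozen=True)
class WellPhenotype:
    """Simulated morphology of one well with its rendered area fraction."""

    state: WellState
    area_fraction: float  # of the circular ROI area
    ground_truth_positive: bool


@dataclass(frozen=True)
class RenderParams:
    """Tunable knobs of the simulated assay and camera.

    ``theta_ng`` is the smallest analyte amount that agglutinates (200 ng by
    default, matching the package-wide detection threshold);
    ``logistic_width`` (log2 units) sets how sharp the amount-to-positivity
    transition is (0 = hard step).  ``edge_effect_amount_ng`` is the analyte
    amount above which the edge-effect artifact may appear; the default sits
    roughly 9-10 two-fold steps above theta, where crude bean extracts show
    it but purified control preparations usually do not.  Pellet areas
    get bounded uniform jitter of ``pellet_jitter_frac`` relative half-width;
    ``rbc_age_offset_frac`` shifts the whole pellet band, emulating red
    blood cell aging between runs.
    """

    theta_ng: float = 200.0
    logistic_width: float = 0.15
    edge_effect_amount_ng: float = 150_000.0
    edge_effect_prob: float = 1.0
    noise_sd: float = 2.0
    illumination_gradient: float = 0.03
    pellet_area_fraction: float = 0.04
    pellet_jitter_frac: float = 0.10
    mat_area_fraction: float = 0.85
    center_jitter_px: float = 1.0
    rbc_age_offset_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta_ng <= 0:
            raise ValueError("theta must be positive")
        if self.noise_sd < 0 or self.illumination_gradient < 0:
            raise ValueError("noise and gradient must be non-negative")


@dataclass(frozen=True)
class RowSpec:
    """One plate row: its role, sample, and dilution series.

    ``series`` describes what was loaded into well 1 (None for a PBS row:
    zero analyte everywhere).  For powder extracts, ``analyte_mass_fraction``
    converts the powder mass per well into active-analyte mass; purified
    controls use 1.0.
    """

    sample_id: str
    role: Literal["positive_control", "sample", "negative_control"]
    series: DilutionSeries | None = None
    analyte_mass_fraction: float = 1.0


@dataclass
class PlateRender:
    """Rendered plate image(s) plus the per-well ground-truth table."""

    images: list[np.ndarray]  # uint8 RGB, one per physical plate
    truth: pd.DataFrame
    geometry: PlateGeometry
    scale: PixelScale
    grids: list[RoiGrid]
    anchor_px: tuple[float, float]
    params: RenderParams

    def truth_last_positive(self, row: int) -> int | None:
        """Ground-truth last positive well index of one 1-based row."""
        t = self.truth[(self.truth["row"] == row) & self.truth["ground_truth_positive"]]
        return int(t["well"].max()) if len(t) else None


def simulate_phenotype(
    amount_ng: float, params: RenderParams, rng: np.random.Generator
) -> WellPhenotype:
    """Draw the phenotype of a well holding ``amount_ng`` of analyte."""
    if amount_ng < 0:
        raise ValueError("analyte amount must be non-negative")
    if amount_ng == 0:
        positive = False
    elif params.logistic_width <= 1e-9:
        positive = amount_ng >= params.theta_ng
    else:
        x = math.log2(amount_ng / params.theta_ng) / params.logistic_width
        p = 1.0 / (1.0 + math.exp(-min(max(x, -700.0), 700.0)))
        positive = rng.random() < p
    if not positive:
        frac = params.pellet_area_fraction * (1.0 + params.rbc_age_offset_frac)
        # bounded two-sided shell jitter: |delta| in [h/2, h].  Its SD is a
        # large fraction of its support, so the mean+3SD threshold estimated
        # from a finite negative-control row reliably clears every pellet.
        h = params.pellet_jitter_frac
        delta = (1.0 if rng.random() < 0.5 else -1.0) * rng.uniform(0.5 * h, h)
        return WellPhenotype("pellet", frac * (1.0 + delta), False)
    ratio = amount_ng / params.theta_ng
    if amount_ng >= params.edge_effect_amount_ng and rng.random() < params.edge_effect_prob:
        return WellPhenotype("edge_polygon", rng.uniform(0.010, 0.020), True)
    if ratio >= 8.0:
        frac = params.mat_area_fraction * (1.0 + 0.04 * (2.0 * rng.random() - 1.0))
        return WellPhenotype("mat", frac, True)
    if ratio >= 2.0:
        state: WellState = "donut" if rng.random() < 0.5 else "fuzzy_mat"
        return WellPhenotype(state, rng.uniform(0.40, 0.55), True)
    return WellPhenotype("fuzzy_mat", rng.uniform(0.28, 0.38), True)


def _paint(canvas: np.ndarray, mask: np.ndarray, y0: int, x0: int, color: tuple[int, int, int]) -> None:
    h, w = mask.shape
    canvas[y0 : y0 + h, x0 : x0 + w][mask] = color


def _window(canvas: np.ndarray, cx: float, cy: float, half: float):
    y0 = max(int(cy - half), 0)
    y1 = min(int(cy + half) + 2, canvas.shape[0])
    x0 = max(int(cx - half), 0)
    x1 = min(int(cx + half) + 2, canvas.shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    return y0, x0, (xx - cx), (yy - cy)


def _render_well(
    canvas: np.ndarray,
    cx: float,
    cy: float,
    roi_radius: float,
    ph: WellPhenotype,
    rng: np.random.Generator,
    params: RenderParams,
) -> None:
    cx = cx + params.center_jitter_px * (2.0 * rng.random() - 1.0)
    cy = cy + params.center_jitter_px * (2.0 * rng.random() - 1.0)
    color = _COLORS[ph.state]
    roi_area = math.pi * roi_radius**2
    y0, x0, dx, dy = _window(canvas, cx, cy, roi_radius + 2)
    if ph.state in ("mat", "pellet"):
        r = math.sqrt(ph.area_fraction) * roi_radius
        _paint(canvas, dx**2 + dy**2 <= r**2, y0, x0, color)
    elif ph.state == "fuzzy_mat":
        # oblong ellipse of matching area, random orientation
        q = rng.uniform(1.1, 1.45)
        a = math.sqrt(ph.area_fraction) * roi_radius * math.sqrt(q)
        b = math.sqrt(ph.area_fraction) * roi_radius / math.sqrt(q)
        phi = rng.uniform(0.0, math.pi)
        u = dx * math.cos(phi) + dy * math.sin(phi)
        v = -dx * math.sin(phi) + dy * math.cos(phi)
        _paint(canvas, (u / a) ** 2 + (v / b) ** 2 <= 1.0, y0, x0, color)
    elif ph.state == "donut":
        hole = 0.45  # hole radius as a fraction of the outer radius
        r_out = roi_radius * math.sqrt(ph.area_fraction / (1.0 - hole**2))
        r_in = hole * r_out
        d2 = dx**2 + dy**2
        _paint(canvas, (d2 <= r_out**2) & (d2 > r_in**2), y0, x0, color)
    else:  # edge_polygon: a few small polygons near the well wall
        k = int(rng.integers(2, 5))
        area_each = ph.area_fraction * roi_area / k
        circum = math.sqrt(area_each / 1.3)  # ~equilateral triangle area 1.3 c^2
        for _ in range(k):
            ang = rng.uniform(0.0, 2.0 * math.pi)
            pcx = cx + 0.65 * roi_radius * math.cos(ang)
            pcy = cy + 0.65 * roi_radius * math.sin(ang)
            verts = rng.uniform(0.0, 2.0 * math.pi) + np.array([0.0, 2.1, 4.2]) + rng.uniform(
                -0.3, 0.3, size=3
            )
            rr, cc = _sk_polygon(
                pcy + circum * np.sin(verts), pcx + circum * np.cos(verts), canvas.shape[:2]
            )
            canvas[rr, cc] = color


def render_plate(
    layout: Sequence[RowSpec],
    geometry: PlateGeometry | None = None,
    scale: PixelScale = PixelScale(0.1),
    params: RenderParams = RenderParams(),
    rng: np.random.Generator | None = None,
) -> PlateRender:
    """Render a plate layout to one or more photographs with ground truth.

    Each layout row occupies one plate row; series longer than the plate
    width continue at the same row of the next rendered plate (the two-plate
    24-well convention).  The returned truth table lists, per well: plate,
    row, global well index, analyte amount (ng), phenotype state, nominal
    area fraction, and ground-truth positivity.
    """
    if geometry is None:
        geometry = PlateGeometry(n_rows=max(len(layout), 1))
    if len(layout) > geometry.n_rows:
        raise ConfigError(
            f"layout has {len(layout)} rows but the plate geometry only {geometry.n_rows}"
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)

    n_wells_max = max((r.series.n_wells if r.series else geometry.n_cols) for r in layout)
    n_plates = math.ceil(n_wells_max / geometry.n_cols)
    pitch_px = scale.px(geometry.well_pitch_mm)
    margin = pitch_px
    height = int(round((geometry.n_rows - 1) * pitch_px + 2 * margin))
    width = int(round((geometry.n_cols - 1) * pitch_px + 2 * margin))
    anchor = (margin, margin)
    grid = build_roi_grid(geometry, scale, anchor)
    roi_radius = grid.radius_px

    canvases = [np.full((height, width, 3), 255, dtype=np.float64) for _ in range(n_plates)]
    records: list[dict] = []
    for row_idx, spec in enumerate(layout, start=1):
        n_wells = spec.series.n_wells if spec.series else n_plates * geometry.n_cols
        for well in range(1, n_wells + 1):
            if spec.series is None:
                amount = 0.0
            else:
                amount = amount_in_well(spec.series, well) * spec.analyte_mass_fraction
            ph = simulate_phenotype(amount, params, rng)
            plate_idx = (well - 1) // geometry.n_cols
            col = (well - 1) % geometry.n_cols + 1
            a = next(x for x in grid.row_anchors(row_idx) if x.col == col)
            _render_well(
                canvases[plate_idx], a.center_x_px, a.center_y_px, roi_radius, ph, rng, params
            )
            records.append(
                {
                    "plate": plate_idx,
                    "row": row_idx,
                    "well": well,
                    "role": spec.role,
                    "sample_id": spec.sample_id,
                    "amount_ng": amount,
                    "state": ph.state,
                    "area_fraction": ph.area_fraction,
                    "ground_truth_positive": ph.ground_truth_positive,
                }
            )

    images: list[np.ndarray] = []
    for canvas in canvases:
        if params.illumination_gradient > 0:
            ang = rng.uniform(0.0, 2.0 * math.pi)
            yy, xx = np.mgrid[0:height, 0:width]
            ramp = (xx * math.cos(ang) + yy * math.sin(ang)).astype(np.float64)
            ramp -= ramp.min()
            if ramp.max() > 0:
                ramp /= ramp.max()
            canvas *= (1.0 - params.illumination_gradient * ramp)[..., None]
        if params.noise_sd > 0:
            canvas += rng.normal(0.0, params.noise_sd, size=canvas.shape)
        images.append(np.clip(np.rint(canvas), 0, 255).astype(np.uint8))

    return PlateRender(
        images=images,
        truth=pd.DataFrame.from_records(records),
        geometry=geometry,
        scale=scale,
        grids=[grid] * n_plates,
        anchor_px=anchor,
        params=params,
    )


def write_render(render: PlateRender, out_dir, prefix: str = "plate") -> list[str]:
    """Write plate_NNN.png, a ground-truth CSV, and a params provenance YAML."""
    import pathlib

    import imageio.v3 as iio
    import yaml

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    for i, img in enumerate(render.images):
        p = out / f"{prefix}_{i:03d}.png"
        iio.imwrite(p, img)
        written.append(str(p))
    truth_path = out / f"{prefix}.truth.csv"
    render.truth.to_csv(truth_path, index=False)
    written.append(str(truth_path))
    params_path = out / "params.yaml"
    provenance = {
        "params": asdict(render.params),
        "geometry": asdict(render.geometry),
        "scale": {"mm_per_px": render.scale.mm_per_px},
        "anchor_px": list(render.anchor_px),
    }
    params_path.write_text(yaml.safe_dump(provenance, sort_keys=False))
    written.append(str(params_path))
    return written
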