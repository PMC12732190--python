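"""Physical plate model, pixel-scale calibration, and ROI-grid construction.

A 96-well round-bottom plate is described by its grid (rows x columns), the
manufacturer's well-bottom diameter, and the center-to-center well pitch.
The pixel scale of a photograph is calibrated from the measured edge-to-edge
pixel width of one well bottom and the known physical diameter.  A grid of
circular regions of interest (ROIs), each covering slightly less than one
well bottom, is then laid out row-major from a single anchor well center.

Coordinates follow image convention: origin top-left, x rightward, y
downward.  Wells are 1-based; the column index equals the serial-dilution
step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

from .errors import CalibrationError

__all__ = [
    "PlateGeometry",
    "PixelScale",
    "RoiAnchor",
    "RoiGrid",
    "calibrate_scale",
    "build_roi_grid",
]


@dataclass(frozen=True)
class PlateGeometry:
    """Physical and grid description of a microplate.

    Parameters
    ----------
    n_rows, n_cols
        Plate grid; a standard 96-well plate is 8 x 12.
    well_bottom_diameter_mm
        Manufacturer's well-bottom diameter.  This is a plate-specific
        config value; 6.4 mm is a typical round-bottom plate and is used
        by the synthetic renderer.
    well_pitch_mm
        Center-to-center well spacing; 9.0 mm is the ANSI/SLAS standard.
    roi_fraction
        Fraction of the well-bottom diameter covered by each circular ROI
        (slightly below 1 so the ROI stays inside the well wall).
    """

    n_rows: int = 8
    n_cols: int = 12
    well_bottom_diameter_mm: float = 6.4
    well_pitch_mm: float = 9.0
    roi_fraction: float = 0.95

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 2:
            raise ValueError("plate grid must have >= 1 row and >= 2 columns")
        if not (0.0 < self.roi_fraction <= 1.0):
            raise ValueError("roi_fraction must be in (0, 1]")
        if self.well_bottom_diameter_mm <= 0:
            raise ValueError("well_bottom_diameter_mm must be positive")
        if self.well_pitch_mm < self.well_bottom_diameter_mm:
            raise ValueError("well pitch cannot be smaller than the well diameter")


@dataclass(frozen=True)
class PixelScale:
    """Isotropic physical scale of an image, in mm per pixel."""

    mm_per_px: float

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be positive")

    def px(self, mm: float) -> float:
        """Convert a physical length in mm to pixels."""
        return mm / self.mm_per_px


class RoiAnchor(NamedTuple):
    """One circular ROI: 1-based grid position, pixel center and radius."""

    row: int
    col: int
    center_x_px: float
    center_y_px: float
    radius_px: float


@dataclass(frozen=True)
class RoiGrid:
    """Row-major ordered circular ROIs superimposed over the well bottoms."""

    anchors: tuple[RoiAnchor, ...]
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if len(self.anchors) != self.n_rows * self.n_cols:
            raise ValueError("anchor count must equal n_rows * n_cols")
        radii = {a.radius_px for a in self.anchors}
        if len(radii) > 1:
            raise ValueError("all ROI radii must be equal")
        for r in range(1, self.n_rows + 1):
            xs = [a.center_x_px for a in self.anchors if a.row == r]
            if any(b <= a for a, b in zip(xs, xs[1:])):
                raise ValueError("ROI centers must increase left-to-right within a row")

    @property
    def radius_px(self) -> float:
        return self.anchors[0].radius_px

    def row_anchors(self, row: int) -> list[RoiAnchor]:
        """ROIs of one 1-based row, ordered by column."""
        return [a for a in self.anchors if a.row == row]

    def __iter__(self) -> Iterator[RoiAnchor]:
        return iter(self.anchors)


def calibrate_scale(well_edge_to_edge_px: float, well_bottom_diameter_mm: float) -> PixelScale:
    """Calibrate the image scale from one measured well bottom.

    The scale is the known physical well-bottom diameter divided by its
    measured edge-to-edge pixel width.

    Raises
    ------
    CalibrationError
        If either length is not strictly positive.
    """
    if well_edge_to_edge_px <= 0 or well_bottom_diameter_mm <= 0:
        raise CalibrationError(
            "calibration lengths must be positive, got "
            f"{well_edge_to_edge_px} px and {well_bottom_diameter_mm} mm"
        )
    return PixelScale(mm_per_px=well_bottom_diameter_mm / well_edge_to_edge_px)


def build_roi_grid(
    geometry: PlateGeometry,
    scale: PixelScale,
    first_well_center_px: tuple[float, float],
) -> RoiGrid:
    """Lay out the ROI grid row-major from the top-left well center.

    Centers are spaced by the well pitch converted to pixels; every ROI has
    radius ``roi_fraction * well_bottom_diameter_mm / (2 * mm_per_px)``.
    Whether the grid fits inside a particular image is checked at
    measurement time, not here.
    """
    x0, y0 = first_well_center_px
    pitch_px = scale.px(geometry.well_pitch_mm)
    radius_px = geometry.roi_fraction * geometry.well_bottom_diameter_mm / (2.0 * scale.mm_per_px)
    anchors = tuple(
        RoiAnchor(
            row=r,
            col=c,
            center_x_px=x0 + (c - 1) * pitch_px,
            center_y_px=y0 + (r - 1) * pitch_px,
            radius_px=radius_px,
        )
        for r in range(1, geometry.n_rows + 1)
        for c in range(1, geometry.n_cols + 1)
    )
    return RoiGrid(anchors=anchors, n_rows=geometry.n_rows, n_cols=geometry.n_cols)
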