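"""Grayscale conversion, per-ROI thresholding, and area/centroid measurement.

This is the particle-analysis stage of the pipeline: plate photographs are
converted to 8-bit grayscale, each circular ROI is extracted against a white
background, pixels at or below the gray threshold (default 235 of 255) are
segmented, and the thresholded area (in mm^2) plus intensity-free centroid is
reported per well.  Agglutinated mats produce large areas; settled negative
pellets produce small compact ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.transform import rotate as _sk_rotate

from .errors import FormatError, MeasurementError
from .geometry import PixelScale, RoiAnchor, RoiGrid

__all__ = [
    "PlateImage",
    "RoiMask",
    "WellMeasurement",
    "DEFAULT_THRESHOLD_GRAY",
    "to_grayscale_8bit",
    "preprocess",
    "extract_and_threshold",
    "measure_wells",
    "measure_plate",
    "measurements_to_frame",
]

#: Inclusive upper gray level counted as signal (0-235 of 0-255).
DEFAULT_THRESHOLD_GRAY = 235


@dataclass(frozen=True)
class PlateImage:
    """An 8-bit grayscale plate photograph with an optional physical scale."""

    pixels: np.ndarray  # 2-D uint8
    scale: PixelScale | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.dtype != np.uint8:
            raise FormatError("PlateImage requires a 2-D uint8 raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RoiMask:
    """Binary segmentation of one ROI, stored on its bounding box."""

    anchor: RoiAnchor
    mask: np.ndarray  # 2-D bool, bounding box of the ROI disk
    origin: tuple[int, int]  # (x0, y0) of the bounding box in image coords


@dataclass(frozen=True)
class WellMeasurement:
    """Thresholded area and centroid of one well.

    ``area_px`` is the raw pixel count; ``area_mm2`` is the pixel count
    scaled by ``mm_per_px**2``.  An empty mask yields area 0 with the
    centroid pinned to the ROI center and ``n_components`` 0.
    """

    row: int
    col: int
    area_mm2: float
    area_px: int
    centroid_x_px: float
    centroid_y_px: float
    n_components: int


def to_grayscale_8bit(
    image: np.ndarray,
    scale: PixelScale | None = None,
    exposure_offset: float = 0.0,
) -> PlateImage:
    """Convert a color or single-channel raster to 8-bit grayscale.

    Color images use the standard luminance weighting (via
    :func:`skimage.color.rgb2gray`); the result is deterministic.  An
    optional linear ``exposure_offset`` (gray levels, may be negative) is
    added after conversion and clipped to [0, 255]; it defaults to 0 and
    exists to mirror in-camera exposure adjustments of real photographs.

    Raises
    ------
    FormatError
        For channel counts other than 1 or 3.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        gray = arr.astype(np.float64)
        if gray.max(initial=0.0) <= 1.0 and np.issubdtype(arr.dtype, np.floating):
            gray = gray * 255.0
    elif arr.ndim == 3 and arr.shape[2] == 3:
        gray = rgb2gray(arr) * 255.0
    else:
        raise FormatError(f"expected 1 or 3 channels, got shape {arr.shape}")
    gray = np.clip(np.rint(gray + exposure_offset), 0, 255).astype(np.uint8)
    return PlateImage(pixels=gray, scale=scale)


def preprocess(
    image: np.ndarray,
    rotation_deg: float = 0.0,
    crop_box: tuple[int, int, int, int] | None = None,
) -> np.ndarray:
    """Explicit rotation/cropping pre-processing of a raw photograph.

    ``rotation_deg`` rotates counter-clockwise about the image center with a
    white fill; ``crop_box`` is (x0, y0, x1, y1), half-open.  Both are
    manual, config-supplied steps — the package deliberately does not
    auto-detect plate pose.
    """
    arr = np.asarray(image)
    if rotation_deg != 0.0:
        as_float = arr.astype(np.float64) / 255.0
        arr = np.clip(
            np.rint(_sk_rotate(as_float, rotation_deg, cval=1.0, preserve_range=True) * 255.0),
            0,
            255,
        ).astype(np.uint8)
    if crop_box is not None:
        x0, y0, x1, y1 = crop_box
        arr = arr[y0:y1, x0:x1]
    return arr


def _disk_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    cx, cy = center
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2


def extract_and_threshold(
    image: PlateImage,
    grid: RoiGrid,
    row: int,
    threshold_max: int = DEFAULT_THRESHOLD_GRAY,
) -> list[RoiMask]:
    """Segment every ROI of one plate row.

    Pixels outside each circular ROI are excluded (treated as white
    background, as when the ROI is lifted onto a blank canvas); within the
    ROI a pixel is signal when its gray value lies in ``[0, threshold_max]``
    (inclusive upper bound).

    Raises
    ------
    MeasurementError
        If any ROI of the row extends beyond the image bounds.
    """
    h, w = image.shape
    out: list[RoiMask] = []
    for anchor in grid.row_anchors(row):
        r = anchor.radius_px
        x0 = int(np.floor(anchor.center_x_px - r))
        x1 = int(np.ceil(anchor.center_x_px + r)) + 1
        y0 = int(np.floor(anchor.center_y_px - r))
        y1 = int(np.ceil(anchor.center_y_px + r)) + 1
        if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
            raise MeasurementError(
                f"ROI for row {anchor.row}, col {anchor.col} exceeds image bounds "
                f"({w}x{h} px)"
            )
        window = image.pixels[y0:y1, x0:x1]
        disk = _disk_mask(window.shape, (anchor.center_x_px - x0, anchor.center_y_px - y0), r)
        mask = disk & (window <= threshold_max)
        out.append(RoiMask(anchor=anchor, mask=mask, origin=(x0, y0)))
    return out


def measure_wells(masks: list[RoiMask], scale: PixelScale) -> list[WellMeasurement]:
    """Measure area and centroid of each ROI mask of one row.

    Multiple connected components within one ROI are summed into a single
    area (``n_components`` records the count for diagnostics).  Results are
    ordered by ascending centroid x, i.e. left-to-right well position.
    """
    out: list[WellMeasurement] = []
    for rm in masks:
        area_px = int(rm.mask.sum())
        x0, y0 = rm.origin
        if area_px == 0:
            cx, cy = rm.anchor.center_x_px, rm.anchor.center_y_px
            n_comp = 0
        else:
            cy_local, cx_local = ndimage.center_of_mass(rm.mask)
            cx, cy = cx_local + x0, cy_local + y0
            _, n_comp = ndimage.label(rm.mask)
        out.append(
            WellMeasurement(
                row=rm.anchor.row,
                col=rm.anchor.col,
                area_mm2=area_px * scale.mm_per_px**2,
                area_px=area_px,
                centroid_x_px=float(cx),
                centroid_y_px=float(cy),
                n_components=int(n_comp),
            )
        )
    out.sort(key=lambda m: m.centroid_x_px)
    return out


def measure_plate(
    image: PlateImage,
    grid: RoiGrid,
    threshold_max: int = DEFAULT_THRESHOLD_GRAY,
    rows: list[int] | None = None,
) -> list[WellMeasurement]:
    """Run extract/threshold/measure over all (or selected) rows of a plate."""
    if image.scale is None:
        raise MeasurementError("PlateImage has no pixel scale; calibrate first")
    result: list[WellMeasurement] = []
    for row in rows if rows is not None else range(1, grid.n_rows + 1):
        masks = extract_and_threshold(image, grid, row, threshold_max)
        result.extend(measure_wells(masks, image.scale))
    return result


def measurements_to_frame(
    measurements: list[WellMeasurement], plate_id: str = "plate"
) -> pd.DataFrame:
    """Tabulate measurements in the interchange CSV layout."""
    return pd.DataFrame(
        {
            "plate_id": plate_id,
            "row": [m.row for m in measurements],
            "col": [m.col for m in measurements],
            "area_mm2": [m.area_mm2 for m in measurements],
            "centroid_x": [m.centroid_x_px for m in measurements],
            "centroid_y": [m.centroid_y_px for m in measurements],
            "n_components": [m.n_components for m in measurements],
        }
    )
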