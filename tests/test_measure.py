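import numpy as np
import pytest

from hemaquant import (
    FormatError,
    MeasurementError,
    PixelScale,
    PlateGeometry,
    build_roi_grid,
    to_grayscale_8bit,
)
from hemaquant.measure import extract_and_threshold, measure_wells, preprocess


def _single_roi_image(fill=255, size=101, scale=0.1):
    """One-well geometry with its ROI centered in a small canvas."""
    geom = PlateGeometry(n_rows=1, n_cols=2, well_pitch_mm=9.0)
    grid = build_roi_grid(geom, PixelScale(scale), (size // 2, size // 2))
    img = np.full((size, size + int(9.0 / scale)), fill, dtype=np.uint8)
    return img, grid


class TestGrayscale:
    def test_white_and_black_map_to_extremes(self):
        white = np.full((2, 2, 3), 255, dtype=np.uint8)
        black = np.zeros((2, 2, 3), dtype=np.uint8)
        assert to_grayscale_8bit(white).pixels[0, 0] == 255
        assert to_grayscale_8bit(black).pixels[0, 0] == 0

    def test_red_mat_tone_golden_value(self):
        """Luminance conversion of the renderer-style red tone is fixed."""
        img = np.full((2, 2, 3), (180, 40, 40), dtype=np.uint8)
        got = to_grayscale_8bit(img).pixels[0, 0]
        assert got == 70  # frozen from the luminance weighting; within [40, 180]

    def test_grayscale_passthrough_and_exposure_offset(self):
        img = np.full((3, 3), 100, dtype=np.uint8)
        assert to_grayscale_8bit(img, exposure_offset=30.0).pixels[0, 0] == 130
        assert to_grayscale_8bit(img).pixels[0, 0] == 100

    def test_unsupported_channel_count_rejected(self):
        with pytest.raises(FormatError):
            to_grayscale_8bit(np.zeros((4, 4, 5), dtype=np.uint8))


class TestThreshold:
    def test_all_white_roi_is_empty(self):
        img, grid = _single_roi_image(fill=255)
        masks = extract_and_threshold(to_grayscale_8bit(img), grid, row=1)
        assert all(m.mask.sum() == 0 for m in masks)

    def test_boundary_235_in_236_out(self):
        """The 0-235 gray range is inclusive at its upper bound."""
        img235, grid = _single_roi_image(fill=235)
        img236, _ = _single_roi_image(fill=236)
        m235 = extract_and_threshold(to_grayscale_8bit(img235), grid, row=1)[0]
        m236 = extract_and_threshold(to_grayscale_8bit(img236), grid, row=1)[0]
        disk_px = m235.mask.sum()
        assert disk_px > 0 and m236.mask.sum() == 0
        # the fully-set mask covers the whole ROI disk
        r = grid.radius_px
        assert disk_px == pytest.approx(np.pi * r**2, rel=0.01)

    def test_rendered_disk_radius_20_pixel_count(self):
        img, grid = _single_roi_image(fill=255)
        cx, cy = 50, 50
        yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
        img[(xx - cx) ** 2 + (yy - cy) ** 2 <= 20**2] = 120
        mask = extract_and_threshold(to_grayscale_8bit(img), grid, row=1)[0]
        assert abs(int(mask.mask.sum()) - 1257) <= 13  # pi r^2 vs rasterized disk

    def test_roi_out_of_bounds_names_the_well(self):
        geom = PlateGeometry(n_rows=1, n_cols=2)
        grid = build_roi_grid(geom, PixelScale(0.1), (20.0, 20.0))
        img = to_grayscale_8bit(np.full((200, 200), 255, dtype=np.uint8))
        with pytest.raises(MeasurementError, match="row 1, col 1"):
            extract_and_threshold(img, grid, row=1)


class TestMeasure:
    def test_empty_masks_measure_zero_at_roi_center(self):
        geom = PlateGeometry(n_rows=1, n_cols=12)
        grid = build_roi_grid(geom, PixelScale(0.1), (90.0, 90.0))
        img = to_grayscale_8bit(np.full((180, 1180), 255, dtype=np.uint8))
        ms = measure_wells(extract_and_threshold(img, grid, 1), PixelScale(0.1))
        assert len(ms) == 12
        assert [m.col for m in ms] == list(range(1, 13))
        for m in ms:
            anchor = next(a for a in grid.row_anchors(1) if a.col == m.col)
            assert m.area_mm2 == 0 and m.n_components == 0
            assert (m.centroid_x_px, m.centroid_y_px) == (
                anchor.center_x_px,
                anchor.center_y_px,
            )

    def test_disk_area_matches_analytic_mm2(self):
        img, grid = _single_roi_image(fill=255)
        yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
        img[(xx - 50) ** 2 + (yy - 50) ** 2 <= 20**2] = 120
        m = measure_wells(
            extract_and_threshold(to_grayscale_8bit(img), grid, 1), PixelScale(0.1)
        )[0]
        assert m.area_mm2 == pytest.approx(np.pi * 2.0**2, rel=0.01)  # r = 2 mm

    def test_two_components_sum_and_are_counted(self):
        img, grid = _single_roi_image(fill=255)
        yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
        d1 = (xx - 40) ** 2 + (yy - 50) ** 2 <= 6**2
        d2 = (xx - 62) ** 2 + (yy - 50) ** 2 <= 8**2
        img[d1 | d2] = 120
        m = measure_wells(
            extract_and_threshold(to_grayscale_8bit(img), grid, 1), PixelScale(0.1)
        )[0]
        assert m.n_components == 2
        assert m.area_px == int(d1.sum() + d2.sum())  # disjoint shapes sum exactly

    def test_area_scale_covariance(self):
        """The same mask reinterpreted at scale s has area s^2 times px count."""
        img, grid = _single_roi_image(fill=255)
        yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
        img[(xx - 50) ** 2 + (yy - 50) ** 2 <= 15**2] = 120
        masks = extract_and_threshold(to_grayscale_8bit(img), grid, 1)
        a1 = measure_wells(masks, PixelScale(0.1))[0]
        a2 = measure_wells(masks, PixelScale(0.2))[0]
        assert a2.area_mm2 == pytest.approx(4.0 * a1.area_mm2)
        assert a1.area_px == a2.area_px


def test_preprocess_crop_and_rotation_white_fill():
    img = np.full((60, 80), 255, dtype=np.uint8)
    img[10:20, 10:30] = 0
    cropped = preprocess(img, crop_box=(10, 10, 30, 20))
    assert cropped.shape == (10, 20) and (cropped == 0).all()
    rotated = preprocess(img, rotation_deg=45.0)
    assert rotated.shape == img.shape
    assert rotated[0, 0] == 255  # corners filled white, not black
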