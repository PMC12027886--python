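"""Marker detection, calibration, segmentation, and calibrated measures."""

import numpy as np
import pytest

from cugrade import (
    CucumberParams,
    MarkerSet,
    SceneSpec,
    compute_calibration,
    detect_markers,
    measure_cucumber,
    render_scene,
    sample_params,
    segment_cucumber,
)
from cugrade.synthscene import GRADES, MARKER_COLOR
from cugrade.vision import SegmentationResult, _dominance
from cugrade.errors import CalibrationError, MarkerDetectionError, SegmentationError


def _markers(tl, tr, bl, br, half=9.5):
    return MarkerSet(
        top_left=tl, top_right=tr, bottom_left=bl, bottom_right=br, half_size_px=half
    )


class TestDetectMarkers:
    def test_centers_within_one_pixel_of_truth(self, straight_tube_scene):
        image, truth, _ = straight_tube_scene
        found = detect_markers(image)
        for key, (tx, ty) in truth.marker_centers_px.items():
            fx, fy = found.centers[key]
            assert abs(fx - tx) <= 1 and abs(fy - ty) <= 1

    def test_all_white_image_raises(self):
        blank = np.full((100, 100, 3), 255, dtype=np.uint8)
        with pytest.raises(MarkerDetectionError):
            detect_markers(blank)

    def test_rotated_scene_keeps_quadrilateral(self, straight_tube_scene):
        image, _, _ = straight_tube_scene
        h, w = image.shape[:2]
        rot = image[::-1, ::-1].copy()
        a = detect_markers(image)
        b = detect_markers(rot)
        # labels swap diagonally; positions map through p -> (W-1-x, H-1-y)
        x, y = a.top_left
        bx, by = b.bottom_right
        assert abs(bx - (w - 1 - x)) <= 1 and abs(by - (h - 1 - y)) <= 1

    def test_robust_to_pixel_noise(self):
        spec = SceneSpec(background_noise_sd=8.0)
        params = CucumberParams(
            arc_length_cm=20, bend_angle_deg=0, thickness_cm=3, center=(20, 15)
        )
        image, truth = render_scene(spec, params, rng=1)
        found = detect_markers(image)
        for key, (tx, ty) in truth.marker_centers_px.items():
            fx, fy = found.centers[key]
            assert abs(fx - tx) <= 1 and abs(fy - ty) <= 1


class TestCalibration:
    def test_square_layout(self):
        m = _markers((50, 50), (450, 50), (50, 350), (450, 350))
        cal = compute_calibration(m, 40, 30)
        assert cal.px_per_cm_x == pytest.approx(10.0)
        assert cal.px_per_cm_y == pytest.approx(10.0)

    def test_scales_linearly_with_board_size(self):
        m = _markers((50, 50), (450, 50), (50, 350), (450, 350))
        cal = compute_calibration(m, 20, 15)
        assert (cal.px_per_cm_x, cal.px_per_cm_y) == (20.0, 20.0)

    def test_trapezoid_averages_top_and_bottom(self):
        m = _markers((55, 50), (445, 50), (45, 350), (455, 350))
        cal = compute_calibration(m, 40, 30)
        assert cal.px_per_cm_x == pytest.approx(10.0)

    def test_degenerate_quadrilateral_raises(self):
        m = _markers((50, 50), (50, 50), (50, 350), (50, 350))
        with pytest.raises(CalibrationError):
            compute_calibration(m, 40, 30)


class TestSegmentation:
    def test_noiseless_mask_matches_truth_exactly(self, spec, thresholds):
        rng = np.random.default_rng(11)
        for grade in ("AL", "BM", "CS"):
            params = sample_params(grade, thresholds, rng)
            image, truth = render_scene(spec, params, thresholds=thresholds)
            seg = segment_cucumber(image, detect_markers(image))
            assert np.array_equal(seg.mask, truth.mask)

    def test_no_cucumber_raises(self, spec):
        image = np.full(spec.image_shape + (3,), 255, dtype=np.uint8)
        m = spec.marker_px
        for x, y in spec.marker_centers_px().values():
            r0, c0 = int(round(y - (m - 1) / 2)), int(round(x - (m - 1) / 2))
            image[r0 : r0 + m, c0 : c0 + m] = MARKER_COLOR
        with pytest.raises(SegmentationError):
            segment_cucumber(image, detect_markers(image))

    def test_distractor_blob_discarded(self, straight_tube_scene):
        image, truth, _ = straight_tube_scene
        image = image.copy()
        image[40:48, 60:68] = (40, 160, 60)  # small green distractor
        seg = segment_cucumber(image, detect_markers(image))
        assert np.array_equal(seg.mask, truth.mask)

    def test_mask_never_touches_markers(self, spec, thresholds):
        rng = np.random.default_rng(3)
        for grade in GRADES:
            params = sample_params(grade, thresholds, rng)
            image, _ = render_scene(spec, params, thresholds=thresholds)
            seg = segment_cucumber(image, detect_markers(image))
            assert not (seg.mask & _dominance(image, 2, 40)).any()


class TestMeasure:
    def test_arithmetic_from_definition(self):
        mask = np.zeros((400, 400), dtype=bool)
        mask[100:300, 200:230] = True
        mask[100:300:2, :] = mask[100:300:2, :]  # keep simple rectangle
        seg = SegmentationResult(mask=mask, bbox=(100, 200, 300, 230), n_pixels=4800)
        from cugrade import Calibration

        m = measure_cucumber(seg, Calibration(10, 10))
        assert (m.height_cm, m.width_cm, m.area_cm2) == (20.0, 3.0, 48.0)

    def test_straight_tube_measures(self, straight_tube_scene):
        image, _, _ = straight_tube_scene
        mk = detect_markers(image)
        cal = compute_calibration(mk, 40, 30)
        m = measure_cucumber(segment_cucumber(image, mk), cal)
        assert m.height_cm == pytest.approx(20.0, rel=0.02)
        assert m.width_cm == pytest.approx(3.0, rel=0.02)
        assert m.area_cm2 == pytest.approx(60.0, rel=0.03)

    @pytest.mark.parametrize("bends", [(0, 40), (40, 80)])
    def test_width_monotone_in_bend(self, bends, spec):
        widths = []
        for bend in bends:
            params = CucumberParams(
                arc_length_cm=20, bend_angle_deg=bend, thickness_cm=3, center=(20, 15)
            )
            image, _ = render_scene(spec, params)
            mk = detect_markers(image)
            cal = compute_calibration(mk, 40, 30)
            widths.append(measure_cucumber(segment_cucumber(image, mk), cal).width_cm)
        assert widths[1] >= widths[0]

    def test_scale_invariance_two_resolutions(self, thresholds):
        params = sample_params("BM", thresholds, 9)
        measures = []
        for ppc in (10, 20):
            spec = SceneSpec(render_px_per_cm=ppc)
            image, _ = render_scene(spec, params, thresholds=thresholds)
            mk = detect_markers(image)
            cal = compute_calibration(mk, 40, 30)
            measures.append(measure_cucumber(segment_cucumber(image, mk), cal))
        a, b = measures
        assert a.height_cm == pytest.approx(b.height_cm, rel=0.02)
        assert a.width_cm == pytest.approx(b.width_cm, rel=0.02)
        assert a.area_cm2 == pytest.approx(b.area_cm2, rel=0.02)
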