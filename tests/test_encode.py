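"""Canvas composition and the RGB background size-encoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cugrade import (
    Calibration,
    Measure,
    NormRanges,
    SceneSpec,
    build_sample,
    decode_bg,
    encode_bg,
    render_scene,
    sample_params,
)
from cugrade.encode import (
    CANVAS_H,
    CANVAS_W,
    Canvas,
    compose_canvas,
    normalize_measures,
    rescale_crop,
)
from cugrade.errors import ConfigurationError, CropOverflowError, DecodeError
from cugrade.vision import detect_markers, segment_cucumber


unit = st.floats(min_value=0.0, max_value=1.0, allow_nan=False)


class TestNormalize:
    def test_half_range(self):
        m = Measure(height_cm=17, width_cm=5, area_cm2=85)
        assert normalize_measures(m, NormRanges()) == (0.5, 0.5, 0.5)

    def test_overflow_clips_to_one(self):
        m = Measure(height_cm=100, width_cm=100, area_cm2=9999)
        assert normalize_measures(m, NormRanges()) == (1.0, 1.0, 1.0)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ConfigurationError):
            NormRanges(height_max_cm=0)


class TestEncodeDecode:
    @pytest.mark.parametrize(
        "t,rgb",
        [
            ((1, 1, 1), (255, 255, 255)),
            ((0, 0, 0), (0, 0, 0)),  # baseline black background
            ((0.5, 0.2, 0.8), (204, 51, 128)),  # R=area, G=width, B=height
        ],
    )
    def test_channel_assignment(self, t, rgb):
        assert encode_bg(t) == rgb

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            encode_bg((1.2, 0, 0))

    @settings(max_examples=100, deadline=None)
    @given(unit, unit, unit)
    def test_roundtrip_within_quantization(self, h, w, a):
        canvas = Canvas(
            pixels=np.full((CANVAS_H, CANVAS_W, 3), encode_bg((h, w, a)), np.uint8),
            bg_color=encode_bg((h, w, a)),
        )
        dec = decode_bg(canvas)
        assert max(abs(x - y) for x, y in zip(dec, (h, w, a))) <= 1 / 255

    def test_disagreeing_corners_raise(self):
        px = np.zeros((CANVAS_H, CANVAS_W, 3), np.uint8)
        px[0, 0] = (1, 2, 3)
        with pytest.raises(DecodeError):
            decode_bg(Canvas(pixels=px, bg_color=(0, 0, 0)))


class TestCompose:
    def _crop(self):
        crop = np.full((40, 20, 3), 77, np.uint8)
        mask = np.zeros((40, 20), bool)
        mask[5:35, 5:15] = True
        return crop, mask

    def test_background_purity(self):
        crop, mask = self._crop()
        canvas = compose_canvas(crop, mask, (10, 20, 30))
        is_obj = ~np.all(canvas.pixels == (10, 20, 30), axis=-1)
        assert is_obj.sum() == mask.sum()
        assert tuple(canvas.pixels[0, 0]) == (10, 20, 30)

    def test_object_pixels_copied_verbatim(self):
        crop, mask = self._crop()
        canvas = compose_canvas(crop, mask, (0, 0, 0))
        obj = canvas.pixels[~np.all(canvas.pixels == 0, axis=-1)]
        assert (obj == 77).all()

    def test_oversized_crop_rejected(self):
        big = np.zeros((CANVAS_H + 1, 10, 3), np.uint8)
        with pytest.raises(CropOverflowError):
            compose_canvas(big, np.ones(big.shape[:2], bool), (0, 0, 0))


class TestRescaleCrop:
    def _seg(self, image):
        return segment_cucumber(image, detect_markers(image))

    def test_identity_at_canvas_scale(self, straight_tube_scene):
        image, _, _ = straight_tube_scene
        seg = self._seg(image)
        crop, mask = rescale_crop(image, seg, Calibration(10, 10), 10)
        r0, c0, r1, c1 = seg.bbox
        assert crop.shape[:2] == (r1 - r0, c1 - c0)
        assert mask.sum() == seg.n_pixels

    def test_halved_from_double_resolution(self, straight_tube_scene):
        image, _, _ = straight_tube_scene
        seg = self._seg(image)
        crop, _ = rescale_crop(image, seg, Calibration(20, 20), 10)
        r0, c0, r1, c1 = seg.bbox
        assert crop.shape[0] == round((r1 - r0) / 2)

    def test_overflow_guard(self, straight_tube_scene):
        image, _, _ = straight_tube_scene
        seg = self._seg(image)
        # pretending the source is 2 px/cm makes the rescale factor 5x:
        # a 200 px tall crop would become 1000 px on a 340 px canvas
        with pytest.raises(CropOverflowError):
            rescale_crop(image, seg, Calibration(2, 2), 10)


class TestBuildSample:
    def test_without_rgb_background_is_black(self, straight_tube_scene):
        image, _, _ = straight_tube_scene
        canvas, _ = build_sample(image, "without_rgb")
        assert decode_bg(canvas) == (0.0, 0.0, 0.0)

    def test_with_rgb_roundtrips_measures(self, straight_tube_scene):
        image, _, _ = straight_tube_scene
        canvas, measure = build_sample(image, "with_rgb")
        dec = decode_bg(canvas)
        expected = normalize_measures(measure, NormRanges())
        assert max(abs(a - b) for a, b in zip(dec, expected)) <= 1 / 255

    def test_object_area_fixed_across_render_scales(self, thresholds):
        params = sample_params("AM", thresholds, 21)
        counts = []
        for ppc in (10, 20):
            spec = SceneSpec(render_px_per_cm=ppc)
            image, _ = render_scene(spec, params, thresholds=thresholds)
            canvas, _ = build_sample(image, "without_rgb")
            counts.append(int((~np.all(canvas.pixels == 0, axis=-1)).sum()))
        assert abs(counts[0] - counts[1]) / counts[0] <= 0.03

    def test_unknown_variant_rejected(self, straight_tube_scene):
        image, _, _ = straight_tube_scene
        with pytest.raises(ConfigurationError):
            build_sample(image, "rgb")
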