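"""Scene generator: grading rules, sampling round trips, rasterization."""

import numpy as np
import pytest

from cugrade import (
    GRADES,
    CucumberParams,
    GradeThresholds,
    SceneSpec,
    assign_grade,
    generate_dataset,
    render_scene,
    sample_params,
)
from cugrade.errors import ConfigurationError, RenderError


class TestAssignGrade:
    @pytest.mark.parametrize(
        "bend,length,expected",
        [
            (5, 26, "AL"),
            (90, 26, "CM"),  # C class has no L: clamps to M
            (30, 17, "BS"),
            (20, 24, "AL"),  # boundaries are inclusive for A and L
            (20.001, 24, "BM"),
            (60, 20, "BM"),
            (60.001, 20, "CM"),
            (0, 18, "AM"),
            (0, 17.999, "AS"),
            (45, 25, "BM"),  # bent-and-long clamps to M
        ],
    )
    def test_examples(self, bend, length, expected, thresholds):
        params = CucumberParams(
            arc_length_cm=length, bend_angle_deg=bend, thickness_cm=3.0
        )
        assert assign_grade(params, thresholds) == expected

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            GradeThresholds(bend_a_max_deg=60, bend_b_max_deg=20)
        with pytest.raises(ConfigurationError):
            GradeThresholds(size_l_min_cm=18, size_m_min_cm=24)

    def test_self_intersecting_tube_rejected(self):
        # radius of curvature 2.9 cm < thickness/2 is geometrically impossible
        with pytest.raises(ConfigurationError):
            CucumberParams(arc_length_cm=5, bend_angle_deg=100, thickness_cm=18)


class TestSampleParams:
    @pytest.mark.parametrize("grade", GRADES)
    def test_roundtrip_regrades_identically(self, grade, thresholds):
        rng = np.random.default_rng(42)
        for _ in range(25):
            params = sample_params(grade, thresholds, rng)
            assert assign_grade(params, thresholds) == grade

    def test_deterministic_given_seed(self, thresholds):
        a = sample_params("BM", thresholds, 123)
        b = sample_params("BM", thresholds, 123)
        assert a == b

    def test_unknown_grade_rejected(self, thresholds):
        with pytest.raises(ConfigurationError):
            sample_params("XL", thresholds)


class TestRenderScene:
    def test_marker_centers_span_board(self, spec, straight_tube_scene):
        _, truth, _ = straight_tube_scene
        c = truth.marker_centers_px
        assert c["top_right"][0] - c["top_left"][0] == pytest.approx(400)
        assert c["bottom_left"][1] - c["top_left"][1] == pytest.approx(300)

    @pytest.mark.parametrize("ppc,tol", [(10, 0.03), (20, 0.015)])
    def test_mask_area_converges_to_analytic(self, ppc, tol):
        # straight 20 x 3 cm tube: analytic area 60 cm^2
        spec = SceneSpec(render_px_per_cm=ppc)
        params = CucumberParams(
            arc_length_cm=20, bend_angle_deg=0, thickness_cm=3, center=(20, 15)
        )
        _, truth = render_scene(spec, params)
        area = truth.mask.sum() / ppc**2
        assert abs(area - 60.0) / 60.0 <= tol

    def test_bent_mask_area_converges(self):
        spec = SceneSpec(render_px_per_cm=10)
        params = CucumberParams(
            arc_length_cm=20, bend_angle_deg=80, thickness_cm=3, center=(20, 15)
        )
        _, truth = render_scene(spec, params)
        area = truth.mask.sum() / 100.0
        assert abs(area - params.analytic_area_cm2) / 60.0 <= 0.03

    def test_straight_tube_bbox_is_length_by_thickness(self, straight_tube_scene):
        # square caps: bbox is exactly L x t up to one pixel of rasterization
        _, truth, params = straight_tube_scene
        rows = np.flatnonzero(truth.mask.any(axis=1))
        cols = np.flatnonzero(truth.mask.any(axis=0))
        h_px = rows[-1] - rows[0] + 1
        w_px = cols[-1] - cols[0] + 1
        assert abs(h_px - 200) <= 1
        assert abs(w_px - 30) <= 1

    def test_grade_recorded_in_truth(self, spec, thresholds):
        params = sample_params("CS", thresholds, 5)
        _, truth = render_scene(spec, params, thresholds=thresholds)
        assert truth.grade == "CS"

    def test_oversized_cucumber_rejected(self, spec):
        params = CucumberParams(
            arc_length_cm=35, bend_angle_deg=0, thickness_cm=3, center=(20, 15)
        )
        with pytest.raises(RenderError):
            render_scene(spec, params)

    def test_marker_overlap_rejected(self, spec):
        params = CucumberParams(
            arc_length_cm=24, bend_angle_deg=0, thickness_cm=3, center=(2.0, 15),
            orientation_deg=0.0,
        )
        with pytest.raises(RenderError):
            render_scene(spec, params)

    def test_noise_perturbs_background(self):
        spec = SceneSpec(background_noise_sd=5.0)
        params = CucumberParams(
            arc_length_cm=20, bend_angle_deg=0, thickness_cm=3, center=(20, 15)
        )
        img, _ = render_scene(spec, params, rng=0)
        corner = img[:5, :5].astype(int)
        assert corner.std() > 0


class TestGenerateDataset:
    def test_counts_names_and_determinism(self, tmp_path):
        m1 = generate_dataset(2, tmp_path / "a", seed=3)
        files = sorted(p.name for p in (tmp_path / "a").glob("*.png"))
        assert len(files) == 14
        assert files[0] == "AL_0001.png"
        assert all(f.split("_")[0] in GRADES for f in files)
        m2 = generate_dataset(2, tmp_path / "b", seed=3)
        assert m1.read_bytes() == m2.read_bytes()

    def test_per_grade_mapping(self, tmp_path):
        counts = dict(zip(GRADES, [3, 2, 1, 1, 1, 1, 1]))
        generate_dataset(counts, tmp_path / "c", seed=0)
        assert len(list((tmp_path / "c").glob("AL_*.png"))) == 3
        assert len(list((tmp_path / "c").glob("*.png"))) == 10

    def test_invalid_count_rejected(self, tmp_path):
        with pytest.raises(ConfigurationError):
            generate_dataset(0, tmp_path / "d")
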