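"""Cobb angle, scapular-triangle asymmetry, grading and fusion routing."""

import math

import numpy as np
import pytest

from scolioscreen.coronal import (
    cobb_angle,
    fusion_report,
    grade_from_cobb,
    grade_from_triangle,
    triangle_angle_diff,
)
from scolioscreen.errors import (
    ConfigError,
    DegenerateTriangleError,
    DomainError,
    InconsistentInputError,
)
from scolioscreen.spine_curve import (
    CurveTypeResult,
    TangentPoint,
    analyze_curve,
    fit_spine_polynomial,
)
from scolioscreen.synth import gen_coronal_case

from conftest import make_keypoints, sine_spine


class TestCobb:
    def test_straight_spine_measures_zero(self, straight_kp):
        curve, tr = analyze_curve(straight_kp)
        assert tr.degenerate
        assert cobb_angle(curve, tr).total_angle == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_arc_matches_analytic_value(self):
        """d(t)=0.1L*4(t/L)(1-t/L): end slopes are -+0.4, so the angle is
        2*atan(0.4) ~= 43.60 degrees."""
        L = 800.0
        t = np.linspace(0, L, 5)
        pts = np.c_[400 + 0.1 * L * 4 * (t / L) * (1 - t / L), 100 + t]
        curve, tr = (fit_spine_polynomial(pts), None)
        from scolioscreen.spine_curve import classify_curve_type, detect_tangent_points

        tr = classify_curve_type(detect_tangent_points(curve))
        result = cobb_angle(curve, tr)
        assert result.total_angle == pytest.approx(2 * math.degrees(math.atan(0.4)), abs=0.05)
        assert len(result.segments) == 1

    def test_s_curve_accumulates_two_segments(self):
        """The S archetype splits at its inflection; segment angles follow the
        quartic's endpoint/centre slopes and sum."""
        A, L = 0.05, 800.0
        curve, tr = analyze_curve_from_points(sine_spine("S", A, length=L))
        result = cobb_angle(curve, tr)
        assert len(result.segments) == 2
        # quartic through (0, A, 0, -A, 0): |slope| = 32A/3 at the ends and
        # 16A/3 at the inflection, per exact polynomial calculus
        per_part = math.degrees(math.atan(32 * A / 3) + math.atan(16 * A / 3))
        assert result.total_angle == pytest.approx(2 * per_part, abs=0.1)

    def test_total_is_sum_of_segments(self):
        curve, tr = analyze_curve_from_points(sine_spine("multi", 0.08))
        result = cobb_angle(curve, tr)
        assert result.total_angle == pytest.approx(sum(s.angle for s in result.segments))
        assert all(0 <= s.angle < 180 for s in result.segments)

    def test_label_apex_mismatch_raises(self):
        curve, _ = analyze_curve_from_points(sine_spine("C", 0.05))
        fake = CurveTypeResult(
            label="C",
            tangent_points=[TangentPoint(300.0, "pos_to_neg", 1e-3),
                            TangentPoint(600.0, "neg_to_pos", 1e-3)],
        )
        with pytest.raises(InconsistentInputError):
            cobb_angle(curve, fake)

    def test_rigid_motion_and_scale_invariance(self):
        base = gen_coronal_case("C", amplitude=0.08).keypoints
        curve, tr = analyze_curve(base)
        ref = cobb_angle(curve, tr).total_angle
        moved = base.translated(123.0, 45.0)
        curve2, tr2 = analyze_curve(moved)
        assert cobb_angle(curve2, tr2).total_angle == pytest.approx(ref, abs=1e-6)
        pts = base.spine_xy() * 1.7
        curve3, tr3 = analyze_curve_from_points(pts)
        assert cobb_angle(curve3, tr3).total_angle == pytest.approx(ref, abs=1e-6)

    def test_mirroring_preserves_angle(self):
        pts = sine_spine("S", 0.07)
        m = pts.copy()
        m[:, 0] = 800.0 - m[:, 0]
        a = cobb_angle(*analyze_curve_from_points(pts)).total_angle
        b = cobb_angle(*analyze_curve_from_points(m)).total_angle
        assert a == pytest.approx(b, abs=1e-9)

    def test_monotone_in_amplitude(self):
        angles = [
            cobb_angle(*analyze_curve_from_points(sine_spine("C", a))).total_angle
            for a in np.linspace(0.01, 0.15, 8)
        ]
        assert all(x < y for x, y in zip(angles, angles[1:]))


def analyze_curve_from_points(pts):
    from scolioscreen.spine_curve import classify_curve_type, detect_tangent_points

    curve = fit_spine_polynomial(pts)
    return curve, classify_curve_type(detect_tangent_points(curve))


class TestTriangle:
    def test_isosceles_has_zero_difference(self):
        kp = make_keypoints(scapula_left=(300, 200), scapula_right=(500, 200))
        result = triangle_angle_diff(kp)
        assert result.abs_diff == pytest.approx(0.0, abs=1e-9)

    def test_law_of_cosines_oracle(self):
        """Scapulae at (0,0) and (4,0), spine end at (1,2): base angles are
        acos(1/sqrt5) and acos(3/sqrt13)."""
        kp = make_keypoints(
            spine_x=(1, 1, 1, 1, 1),
            spine_y=(0.5, 1, 1.5, 1.8, 2),
            scapula_left=(0, 0),
            scapula_right=(4, 0),
            width=10,
            height=10,
        )
        result = triangle_angle_diff(kp)
        left = math.degrees(math.acos(1 / math.sqrt(5)))
        right = math.degrees(math.acos(3 / math.sqrt(13)))
        assert result.base_angle_left == pytest.approx(left, abs=1e-9)
        assert result.base_angle_right == pytest.approx(right, abs=1e-9)
        assert result.abs_diff == pytest.approx(abs(left - right), abs=1e-9)

    def test_angle_sum_is_180(self, rng):
        for _ in range(50):
            xy = rng.uniform(10, 700, size=(3, 2))
            kp = make_keypoints(
                spine_x=np.full(5, xy[2, 0]),
                spine_y=np.linspace(100, xy[2, 1] + 300, 5),
                scapula_left=tuple(xy[0]),
                scapula_right=tuple(xy[1]),
                height=1200,
            )
            try:
                r = triangle_angle_diff(kp)
            except DegenerateTriangleError:
                continue
            assert r.base_angle_left + r.base_angle_right + r.apex_angle == pytest.approx(
                180.0, abs=1e-6
            )

    def test_mirror_symmetry(self):
        kp = make_keypoints(scapula_left=(260, 180), scapula_right=(560, 240))
        mirrored = make_keypoints(
            spine_x=tuple(800 - x for x in (400,) * 5),
            scapula_left=(800 - 560, 240),
            scapula_right=(800 - 260, 180),
        )
        assert triangle_angle_diff(kp).abs_diff == pytest.approx(
            triangle_angle_diff(mirrored).abs_diff, abs=1e-9
        )

    def test_collinear_vertices_raise(self):
        kp = make_keypoints(
            spine_x=(400, 400, 400, 400, 400),
            scapula_left=(400, 200),
            scapula_right=(400, 300),
        )
        with pytest.raises(DegenerateTriangleError):
            triangle_angle_diff(kp)


class TestGrading:
    @pytest.mark.parametrize(
        "angle,idx",
        [(0, 0), (5, 0), (9.95, 0), (10, 1), (19.5, 1), (20, 2), (44.9, 2), (45, 3), (70, 3)],
    )
    def test_cobb_class_boundaries(self, angle, idx):
        grade = grade_from_cobb(angle)
        assert grade.class_index == idx
        assert grade.method == "cobb"

    def test_negative_angle_raises(self):
        with pytest.raises(DomainError):
            grade_from_cobb(-1.0)

    def test_cobb_grade_monotone_on_fine_grid(self):
        grid = np.arange(0, 90.05, 0.1)
        classes = [grade_from_cobb(a).class_index for a in grid]
        assert all(a <= b for a, b in zip(classes, classes[1:]))

    @pytest.mark.parametrize("diff,idx", [(0, 0), (1.99, 0), (2, 1), (6, 2), (10, 3)])
    def test_triangle_thresholds(self, diff, idx):
        assert grade_from_triangle(diff, (2, 5, 10)).class_index == idx

    def test_triangle_grade_monotone(self):
        vals = [grade_from_triangle(d, (2, 5, 10)).class_index for d in np.linspace(0, 20, 200)]
        assert all(a <= b for a, b in zip(vals, vals[1:]))

    def test_non_ascending_thresholds_raise(self):
        with pytest.raises(ConfigError):
            grade_from_triangle(3.0, (5, 2, 10))


class TestFusion:
    def test_c_routes_to_triangle(self):
        case = gen_coronal_case("C", amplitude=0.05)
        report = fusion_report(case.keypoints)
        assert report.curve_type == "C"
        assert report.grade.method == "triangle"

    def test_s_routes_to_cobb(self):
        case = gen_coronal_case("S", amplitude=0.05)
        report = fusion_report(case.keypoints)
        assert report.curve_type == "S"
        assert report.grade.method == "cobb"

    def test_straight_spine_grades_mild_via_triangle(self, straight_kp):
        report = fusion_report(straight_kp)
        assert report.degenerate
        assert report.grade.method == "triangle"
        assert report.grade.class_index == 0

    def test_routing_matches_curve_type(self):
        for kind, method in (("C", "triangle"), ("S", "cobb"), ("multi", "cobb")):
            for amp in (0.03, 0.08, 0.13):
                case = gen_coronal_case(kind, amplitude=amp, seed=3)
                assert fusion_report(case.keypoints).grade.method == method
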