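import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneemorph.errors import (
    DegenerateGeometryError,
    EmptyContourError,
    MissingLandmarkError,
    NoTangentError,
    UndefinedBisectorError,
)
from kneemorph.geometry import (
    AngleSet,
    LandmarkAnnotation,
    Point,
    Side,
    angle_at_vertex,
    bisector_angle,
    bisector_direction,
    hka_deviation,
    measure_all,
    mirror_annotation,
    mldfa,
    mmpta,
    tangent_from_point,
    trochlear_angles,
)
from kneemorph.simulate import build_subject_geometry

from conftest import random_annotation, random_feasible_angles, transform_annotation

finite_coord = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


def atan2_angle_oracle(apex, p1, p2):
    """Independent arc-tangent difference oracle for the vertex angle."""
    a1 = math.atan2(p1.y - apex.y, p1.x - apex.x)
    a2 = math.atan2(p2.y - apex.y, p2.x - apex.x)
    d = abs(a1 - a2) % (2 * math.pi)
    if d > math.pi:
        d = 2 * math.pi - d
    return math.degrees(d)


class TestAngleAtVertex:
    def test_orthogonal_rays(self):
        assert angle_at_vertex(Point(0, 0), Point(1, 0), Point(0, 1)) == pytest.approx(90.0, abs=1e-12)

    def test_same_ray(self):
        assert angle_at_vertex(Point(0, 0), Point(1, 0), Point(2, 0)) == pytest.approx(0.0, abs=1e-12)

    def test_atan2_oracle_example(self):
        apex, p1, p2 = Point(0, 0), Point(3, 1), Point(-1, 2)
        expected = atan2_angle_oracle(apex, p1, p2)
        assert angle_at_vertex(apex, p1, p2) == pytest.approx(expected, abs=1e-9)

    def test_coincident_point_raises(self):
        with pytest.raises(DegenerateGeometryError):
            angle_at_vertex(Point(1, 1), Point(1, 1), Point(2, 2))

    @settings(max_examples=200, deadline=None)
    @given(finite_coord, finite_coord, finite_coord, finite_coord)
    def test_matches_oracle_and_range(self, x1, y1, x2, y2):
        apex = Point(0.0, 0.0)
        p1, p2 = Point(x1, y1), Point(x2, y2)
        if math.hypot(x1, y1) < 1e-6 or math.hypot(x2, y2) < 1e-6:
            return
        got = angle_at_vertex(apex, p1, p2)
        assert 0.0 <= got <= 180.0
        assert got == pytest.approx(atan2_angle_oracle(apex, p1, p2), abs=1e-9)
        assert got == pytest.approx(angle_at_vertex(apex, p2, p1), abs=1e-12)


class TestBisectorDirection:
    def test_symmetric_case(self):
        b = bisector_direction(Point(0, 0), Point(1, 0), Point(0, 1))
        assert b[0] == pytest.approx(math.sqrt(2) / 2, abs=1e-12)
        assert b[1] == pytest.approx(math.sqrt(2) / 2, abs=1e-12)

    def test_identical_rays(self):
        b = bisector_direction(Point(0, 0), Point(5, 0), Point(1, 0))
        assert b == pytest.approx((1.0, 0.0), abs=1e-12)

    def test_opposite_rays_raise(self):
        with pytest.raises(UndefinedBisectorError):
            bisector_direction(Point(0, 0), Point(1, 0), Point(-2, 0))

    def test_coincident_with_apex_raises(self):
        with pytest.raises(DegenerateGeometryError):
            bisector_direction(Point(0, 0), Point(0, 0), Point(1, 0))

    @settings(max_examples=200, deadline=None)
    @given(st.floats(-170, 170), st.floats(-80, 80), st.floats(0.1, 10), st.floats(0.1, 10))
    def test_equal_angles_to_both_rays(self, base_deg, half_deg, r1, r2):
        # brute-force rotation oracle: build rays at known polar angles
        a1 = math.radians(base_deg - half_deg)
        a2 = math.radians(base_deg + half_deg)
        apex = Point(0.3, -0.7)
        p1 = Point(apex.x + r1 * math.cos(a1), apex.y + r1 * math.sin(a1))
        p2 = Point(apex.x + r2 * math.cos(a2), apex.y + r2 * math.sin(a2))
        b = bisector_direction(apex, p1, p2)
        tip = Point(apex.x + b[0], apex.y + b[1])
        ang1 = angle_at_vertex(apex, p1, tip)
        ang2 = angle_at_vertex(apex, p2, tip)
        assert ang1 == pytest.approx(ang2, abs=1e-9)
        total = angle_at_vertex(apex, p1, p2)
        assert total == pytest.approx(2 * ang1, abs=1e-9)


def circle_tangency_oracle(apex, center, radius, sign):
    """Closed-form point-to-circle tangency (sign picks one of the two)."""
    dx, dy = apex.x - center[0], apex.y - center[1]
    d = math.hypot(dx, dy)
    beta = math.acos(radius / d)
    base = math.atan2(dy, dx)
    phi = base + sign * beta
    return Point(center[0] + radius * math.cos(phi), center[1] + radius * math.sin(phi))


class TestTangentFromPoint:
    def test_single_point_contour(self):
        p = Point(2.0, 3.0)
        assert tangent_from_point(Point(0, 0), [p], "medial", Side.RIGHT) is p

    def test_empty_contour_raises(self):
        with pytest.raises(EmptyContourError):
            tangent_from_point(Point(0, 0), [], "medial", Side.RIGHT)

    def test_apex_inside_hull_raises(self):
        square = [Point(-1, -1), Point(1, -1), Point(1, 1), Point(-1, 1)]
        with pytest.raises(NoTangentError):
            tangent_from_point(Point(0, 0), square, "medial", Side.RIGHT)

    def test_tie_break_farther_point(self):
        contour = [Point(1, 1), Point(2, 2), Point(1, 0)]
        got = tangent_from_point(
            Point(0, 0), contour, "medial", Side.RIGHT, medial_direction=(1.0, -1.0)
        )
        assert got == Point(2, 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_circle_arc_matches_analytic_tangency(self, seed):
        rng = np.random.default_rng(seed)
        center = (rng.uniform(-2, 2), rng.uniform(-6, -4))
        radius = rng.uniform(1.0, 2.0)
        apex = Point(0.0, 0.0)
        n_pts = 400
        # arc facing the apex, wide enough to contain both tangency points
        d = math.hypot(apex.x - center[0], apex.y - center[1])
        beta = math.acos(radius / d)
        base = math.atan2(apex.y - center[1], apex.x - center[0])
        half_span = beta + 0.2
        phis = base + np.linspace(-half_span, half_span, n_pts)
        contour = [
            Point(center[0] + radius * math.cos(p), center[1] + radius * math.sin(p))
            for p in phis
        ]
        dm = (1.0, 0.0)
        for branch in ("medial", "lateral"):
            got = tangent_from_point(
                apex, contour, branch, Side.RIGHT, medial_direction=dm
            )
            # oracle: the tangency whose line leaves the circle on the branch side
            want = None
            for s in (-1.0, 1.0):
                t = circle_tangency_oracle(apex, center, radius, s)
                u = (t.x - apex.x, t.y - apex.y)
                circle_side = u[0] * (center[1] - apex.y) - u[1] * (center[0] - apex.x)
                branch_side = u[0] * dm[1] - u[1] * dm[0]
                if branch == "lateral":
                    branch_side = -branch_side
                if circle_side * branch_side > 0:
                    want = t
            assert want is not None
            spacing = 2 * half_span * radius / (n_pts - 1)
            assert math.hypot(got.x - want.x, got.y - want.y) <= spacing + 1e-9

    def test_supporting_half_plane_property(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            pts = [Point(float(x), float(y)) for x, y in rng.uniform(-1, 1, size=(8, 2))]
            apex = Point(0.0, 5.0)
            got = tangent_from_point(apex, pts, "medial", Side.RIGHT)
            u = (got.x - apex.x, got.y - apex.y)
            nu = math.hypot(*u)
            crosses = [
                (u[0] * (q.y - apex.y) - u[1] * (q.x - apex.x)) / nu for q in pts
            ]
            assert all(c >= -1e-12 for c in crosses) or all(c <= 1e-12 for c in crosses)


class TestTrochlearAngles:
    def test_symmetric_configuration(self):
        ann = LandmarkAnnotation(
            "s", Side.RIGHT, "o", 1,
            points={
                "trochlear_apex": Point(0, 10),
                "trochlear_tangent_medial": Point(3, 0),
                "trochlear_tangent_lateral": Point(-3, 0),
            },
        )
        tga, tgb = trochlear_angles(ann)
        expected = 2 * math.degrees(math.atan2(3, 10))  # atan2 oracle
        assert tga == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(33.398, abs=1e-3)
        assert tgb == pytest.approx((0.0, 1.0), abs=1e-12)

    def test_coincident_tangents_zero_angle(self):
        ann = LandmarkAnnotation(
            "s", Side.RIGHT, "o", 1,
            points={
                "trochlear_apex": Point(0, 10),
                "trochlear_tangent_medial": Point(1, 0),
                "trochlear_tangent_lateral": Point(1, 0),
            },
        )
        tga, tgb = trochlear_angles(ann)
        assert tga == pytest.approx(0.0, abs=1e-12)
        d = math.hypot(1 - 0, 0 - 10)
        assert tgb == pytest.approx((-1 / d, 10 / d), abs=1e-12)

    def test_bisector_property_random(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            ann, _ = random_annotation(rng)
            apex = ann.points["trochlear_apex"]
            tm = ann.points["trochlear_tangent_medial"]
            tl = ann.points["trochlear_tangent_lateral"]
            tga, tgb = trochlear_angles(ann)
            tip = Point(apex.x - tgb[0], apex.y - tgb[1])  # distal bisector tip
            assert angle_at_vertex(apex, tm, tip) == pytest.approx(tga / 2, abs=1e-9)
            assert angle_at_vertex(apex, tl, tip) == pytest.approx(tga / 2, abs=1e-9)


class TestBisectorAngle:
    @staticmethod
    def _symmetric_annotation(joint_rotation_deg=0.0):
        c, s = (
            math.cos(math.radians(joint_rotation_deg)),
            math.sin(math.radians(joint_rotation_deg)),
        )
        cm = Point(5 * c, 5 * s)
        cl = Point(-5 * c, -5 * s)
        return LandmarkAnnotation(
            "s", Side.RIGHT, "o", 1,
            points={
                "trochlear_apex": Point(0, 10),
                "trochlear_tangent_medial": Point(3, 0),
                "trochlear_tangent_lateral": Point(-3, 0),
                "condyle_medial": cm,
                "condyle_lateral": cl,
            },
        )

    def test_perpendicular_reads_90(self):
        assert bisector_angle(self._symmetric_annotation()) == pytest.approx(90.0, abs=1e-9)

    @pytest.mark.parametrize("rot", [2.0, -2.0, 7.5])
    def test_rotated_joint_line_sign(self, rot):
        # brute-force rotation oracle: lateral->medial vector at angle `rot`,
        # vertical proximal bisector -> angle is 90 - rot
        ann = self._symmetric_annotation(rot)
        assert bisector_angle(ann) == pytest.approx(90.0 - rot, abs=1e-9)

    def test_coincident_condyles_raise(self):
        ann = self._symmetric_annotation()
        ann.points["condyle_lateral"] = ann.points["condyle_medial"]
        with pytest.raises(DegenerateGeometryError):
            bisector_angle(ann)

    def test_round_trip_population_mean(self):
        angles = AngleSet(0.0, 87.6, 88.0, 30.0, 89.4)
        ann = build_subject_geometry(angles)
        assert bisector_angle(ann) == pytest.approx(89.4, abs=1e-9)


class TestHkaDeviation:
    def test_collinear_is_zero(self):
        ann = LandmarkAnnotation(
            "s", Side.RIGHT, "o", 1,
            points={
                "hip_center": Point(0, 100),
                "femoral_notch_center": Point(0, 0),
                "tibial_spines_center": Point(0, -2),
                "ankle_center": Point(0, -100),
            },
        )
        assert hka_deviation(ann) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_varus_is_negative(self):
        ann = build_subject_geometry(AngleSet(-5.0, 90.0, 90.0, 30.0, 90.0))
        assert hka_deviation(ann) == pytest.approx(-5.0, abs=1e-9)

    def test_constructed_valgus_is_positive(self):
        ann = build_subject_geometry(AngleSet(4.0, 90.0, 90.0, 30.0, 90.0))
        assert hka_deviation(ann) == pytest.approx(4.0, abs=1e-9)

    def test_mirror_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            ann, _ = random_annotation(rng)
            assert hka_deviation(mirror_annotation(ann)) == pytest.approx(
                hka_deviation(ann), abs=1e-9
            )


class TestMldfaMmpta:
    def test_perpendicular_is_90(self):
        ann = LandmarkAnnotation(
            "s", Side.RIGHT, "o", 1,
            points={
                "hip_center": Point(0, 100),
                "femoral_notch_center": Point(0, 0),
                "condyle_medial": Point(5, 0),
                "condyle_lateral": Point(-5, 0),
                "tibial_spines_center": Point(0, -1),
                "ankle_center": Point(0, -100),
                "plateau_medial": Point(5, -1),
                "plateau_lateral": Point(-5, -1),
            },
        )
        assert mldfa(ann) == pytest.approx(90.0, abs=1e-12)
        assert mmpta(ann) == pytest.approx(90.0, abs=1e-12)

    def test_mldfa_round_trip(self):
        ann = build_subject_geometry(AngleSet(0.0, 87.6, 88.0, 30.0, 89.4))
        assert mldfa(ann) == pytest.approx(87.6, abs=1e-9)

    def test_mldfa_rotation_invariance(self):
        ann = build_subject_geometry(AngleSet(2.0, 86.0, 91.0, 25.0, 88.0))
        rotated = transform_annotation(ann, angle_deg=33.0)
        assert mldfa(rotated) == pytest.approx(mldfa(ann), abs=1e-9)

    def test_mmpta_round_trip(self):
        ann = build_subject_geometry(AngleSet(0.0, 87.6, 88.0, 30.0, 89.4))
        assert mmpta(ann) == pytest.approx(88.0, abs=1e-9)

    def test_mmpta_scale_invariance(self):
        ann = build_subject_geometry(AngleSet(-3.0, 89.0, 85.0, 40.0, 92.0))
        scaled = transform_annotation(ann, scale=2.7)
        assert mmpta(scaled) == pytest.approx(mmpta(ann), abs=1e-9)


class TestMeasureAll:
    def test_round_trip_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            angles = random_feasible_angles(rng)
            ann = build_subject_geometry(angles)
            got = measure_all(ann)
            for name, want in angles.as_dict().items():
                assert getattr(got, name) == pytest.approx(want, abs=1e-9), name

    def test_translation_invariance(self):
        rng = np.random.default_rng(6)
        ann, _ = random_annotation(rng)
        moved = transform_annotation(ann, dx=1000.0, dy=-500.0)
        a, b = measure_all(ann).as_dict(), measure_all(moved).as_dict()
        for name in a:
            assert b[name] == pytest.approx(a[name], abs=1e-9)

    def test_strict_missing_landmark_named(self):
        rng = np.random.default_rng(7)
        ann, _ = random_annotation(rng)
        del ann.points["ankle_center"]
        with pytest.raises(MissingLandmarkError, match="ankle_center"):
            measure_all(ann, strict=True)

    def test_partial_mode_reports_absent(self):
        rng = np.random.default_rng(8)
        ann, _ = random_annotation(rng)
        del ann.points["ankle_center"]
        got = measure_all(ann, strict=False)
        assert got.hka_deviation is None
        assert got.mmpta is None
        assert got.mldfa is not None and got.ba is not None and got.tga is not None


class TestInvarianceProperties:
    @settings(max_examples=100, deadline=None)
    @given(
        st.integers(0, 10_000),
        st.floats(-180, 180),
        st.floats(0.1, 50.0),
        st.floats(-1e4, 1e4),
        st.floats(-1e4, 1e4),
    )
    def test_rigid_motion_and_scale(self, seed, rot, scale, dx, dy):
        rng = np.random.default_rng(seed)
        ann, _ = random_annotation(rng)
        base = measure_all(ann).as_dict()
        moved = measure_all(
            transform_annotation(ann, angle_deg=rot, scale=scale, dx=dx, dy=dy)
        ).as_dict()
        for name in base:
            assert moved[name] == pytest.approx(base[name], abs=1e-9), name

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10_000))
    def test_mirror_and_side_flip(self, seed):
        rng = np.random.default_rng(seed)
        ann, _ = random_annotation(rng)
        base = measure_all(ann).as_dict()
        mirrored = measure_all(mirror_annotation(ann)).as_dict()
        for name in base:
            assert mirrored[name] == pytest.approx(base[name], abs=1e-9), name
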