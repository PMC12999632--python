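import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sarscan.geometry import (
    BoundingBox,
    ContactSurface,
    CoordinateFrame,
    DegenerateGeometryError,
    EmptyPlanError,
    NegativeDepthError,
    OutOfWorkspaceError,
    Point3,
    ScanPlan,
    build_scan_plan,
    circle_from_three_points,
    emit_gcode,
    parse_gcode,
    surface_from_three_points,
)

finite = st.floats(-100, 100, allow_nan=False, allow_infinity=False)


class TestCircumcircle:
    @pytest.mark.parametrize(
        "pts, center, radius",
        [
            ([(0, 0), (2, 0), (0, 2)], (1, 1), math.sqrt(2)),
            ([(-1, 0), (0, 1), (1, 0)], (0, 0), 1.0),
        ],
    )
    def test_known_circles(self, pts, center, radius):
        c, r = circle_from_three_points(*(Point3(x, 0.0, z) for x, z in pts))
        assert (c.x, c.z) == pytest.approx(center, abs=1e-12)
        assert r == pytest.approx(radius, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(coords=st.lists(finite, min_size=6, max_size=6))
    def test_center_equidistant_and_permutation_invariant(self, coords):
        pts = [Point3(coords[2 * i], 0.0, coords[2 * i + 1]) for i in range(3)]
        (x1, z1), (x2, z2), (x3, z3) = ((p.x, p.z) for p in pts)
        area = 0.5 * abs((x2 - x1) * (z3 - z1) - (x3 - x1) * (z2 - z1))
        if area < 1e-3:
            return  # (near-)degenerate inputs are covered by the error test
        c, r = circle_from_three_points(*pts)
        for p in pts:
            assert math.hypot(p.x - c.x, p.z - c.z) == pytest.approx(
                r, rel=1e-9, abs=1e-9
            )
        c2, r2 = circle_from_three_points(pts[2], pts[0], pts[1])
        assert (c2.x, c2.z) == pytest.approx((c.x, c.z), rel=1e-9, abs=1e-9)

    def test_collinear_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            circle_from_three_points(
                Point3(0, 0, 0), Point3(1, 0, 1), Point3(2, 0, 2)
            )
        with pytest.raises(DegenerateGeometryError):
            circle_from_three_points(
                Point3(0, 0, 0), Point3(0, 0, 0), Point3(1, 0, 1)
            )

    def test_surface_from_reference_depth_points(self):
        # three points on a circle of radius 18.5 -> contact radius 17.5
        r, cz = 18.5, -17.5
        pts = [
            Point3(r * math.sin(t), 0.0, cz + r * math.cos(t))
            for t in (-0.4, 0.05, 0.5)
        ]
        surface, center = surface_from_three_points(*pts, depth_reference=1.0)
        assert surface.radius == pytest.approx(17.5, abs=1e-9)
        assert (center.x, center.z) == pytest.approx((0.0, cz), abs=1e-9)


class TestCoordinateFrame:
    def test_origin_maps_to_zero(self):
        f = CoordinateFrame(origin_in_robot=Point3(10, 20, 5))
        m = f.to_measurement(Point3(10, 20, 5))
        assert (m.x, m.y, m.z) == (0.0, 0.0, 0.0)

    def test_z_flip_makes_depth_positive(self):
        # robot z axis points up: one cm below the origin is depth +1
        f = CoordinateFrame(origin_in_robot=Point3(0, 0, 10), z_sign_flip=True)
        assert f.to_measurement(Point3(0, 0, 9)).z == pytest.approx(1.0)

    @settings(derandomize=True, max_examples=50)
    @given(px=finite, py=finite, pz=finite, flip=st.booleans())
    def test_round_trip_identity(self, px, py, pz, flip):
        f = CoordinateFrame(origin_in_robot=Point3(25, 25, 20), z_sign_flip=flip)
        p = Point3(px, py, pz)
        q = f.to_robot(f.to_measurement(p))
        assert (q.x, q.y, q.z) == pytest.approx((p.x, p.y, p.z), abs=1e-9)


class TestSurfaceCoordinates:
    def test_flat_is_identity(self, flat_surface):
        assert flat_surface.surface_coordinates(Point3(3, -2, 1)) == (3, -2, 1)

    def test_cylinder_arc_length(self, cylinder_surface):
        # point at angle 0.1 rad from apex, 18.5 cm from axis -> u=1.75, depth=1
        r, theta = 17.5, 0.1
        p = Point3(18.5 * math.sin(theta), 4.0, 18.5 * math.cos(theta) - r)
        u, v, depth = cylinder_surface.surface_coordinates(p)
        assert u == pytest.approx(r * theta, abs=1e-9)
        assert v == 4.0
        assert depth == pytest.approx(1.0, abs=1e-9)

    def test_apex_point(self, cylinder_surface):
        u, v, depth = cylinder_surface.surface_coordinates(Point3(0, 2.5, 0))
        assert (u, v, depth) == pytest.approx((0.0, 2.5, 0.0), abs=1e-12)

    def test_above_surface_rejected(self, flat_surface, cylinder_surface):
        with pytest.raises(NegativeDepthError):
            flat_surface.surface_coordinates(Point3(0, 0, -1))
        with pytest.raises(NegativeDepthError):
            cylinder_surface.surface_coordinates(Point3(0, 0, -0.5))

    @settings(derandomize=True, max_examples=50)
    @given(
        u=st.floats(-20, 20), v=st.floats(-20, 20), depth=st.floats(0, 6)
    )
    def test_mapping_invertible(self, u, v, depth):
        surface = ContactSurface(kind="cylinder", radius=17.5)
        p = surface.point_at(u, v, depth)
        got = surface.surface_coordinates(p)
        assert got == pytest.approx((u, v, depth), abs=1e-9)

    def test_flat_is_infinite_radius_limit(self, flat_surface):
        huge = ContactSurface(kind="cylinder", radius=1e6)
        for x in np.linspace(-15, 15, 11):
            for depth in (0.0, 1.0, 5.0):
                p = Point3(x, 2.0, depth)
                uf = flat_surface.surface_coordinates(p)
                uc = huge.surface_coordinates(p)
                assert np.allclose(uf, uc, atol=1e-3)


class TestScanPlan:
    def test_flat_xy_point_count(self, flat_surface, frame, xy_bbox):
        plan = build_scan_plan(flat_surface, frame, xy_bbox, "xy_at_depth", 1.0)
        assert len(plan) == 33 * 25 == 825
        assert np.all(plan.surface_points[:, 2] == 1.0)

    def test_quarter_spacing_count_and_time_ratio(self, flat_surface, frame, xy_bbox):
        plan = build_scan_plan(flat_surface, frame, xy_bbox, "xy_at_depth", 0.25)
        assert len(plan) == 129 * 97 == 12513
        assert len(plan) / 825 == pytest.approx(15.2, abs=0.1)

    def test_points_unique_inside_bbox_and_spaced(self, flat_surface, frame, xy_bbox):
        plan = build_scan_plan(flat_surface, frame, xy_bbox, "xy_at_depth", 1.0)
        sp = plan.surface_points
        assert len(np.unique(sp, axis=0)) == len(sp)
        assert sp[:, 0].min() >= xy_bbox.x[0] and sp[:, 0].max() <= xy_bbox.x[1]
        assert sp[:, 1].min() >= xy_bbox.y[0] and sp[:, 1].max() <= xy_bbox.y[1]
        # consecutive points within a row are exactly one spacing apart in u
        same_row = np.diff(sp[:, 1]) == 0
        du = np.abs(np.diff(sp[:, 0]))[same_row]
        assert np.allclose(du, 1.0)

    def test_reference_curve_scanned_first(self, flat_surface, frame, xy_bbox):
        plan = build_scan_plan(flat_surface, frame, xy_bbox, "xz", 1.0)
        n_row = 33
        assert np.all(plan.surface_points[:n_row, 2] == 1.0)
        deeper = plan.surface_points[n_row:, 2]
        assert np.all(np.diff(np.unique(deeper)) == 1.0)
        assert deeper.min() == 2.0

    def test_cylinder_reference_points_on_offset_cylinder(
        self, cylinder_surface, frame, xy_bbox
    ):
        plan = build_scan_plan(cylinder_surface, frame, xy_bbox, "xz", 1.0)
        n_row = 33
        for p in plan.measurement_points[:n_row]:
            dist = math.hypot(p.x, p.z + 17.5)
            assert dist == pytest.approx(18.5, abs=1e-6)

    def test_volume_layers_by_increasing_depth(self, flat_surface, frame):
        bbox = BoundingBox(x=(-2, 2), y=(-2, 2), z=(1, 3))
        plan = build_scan_plan(flat_surface, frame, bbox, "volume", 1.0)
        assert len(plan) == 5 * 5 * 3
        depths = plan.surface_points[:, 2]
        assert np.all(np.diff(depths) >= 0)

    def test_empty_plan_rejected(self, flat_surface, frame):
        bbox = BoundingBox(x=(0.2, 0.4), y=(-12, 12))
        with pytest.raises(EmptyPlanError):
            build_scan_plan(flat_surface, frame, bbox, "xy_at_depth", 1.0)

    def test_out_of_workspace_on_tight_cylinder(self, frame, xy_bbox):
        tight = ContactSurface(kind="cylinder", radius=3.0)
        with pytest.raises(OutOfWorkspaceError):
            build_scan_plan(tight, frame, xy_bbox, "xy_at_depth", 1.0)


class TestGcode:
    def test_single_point_body(self, flat_surface, frame):
        bbox = BoundingBox(x=(0, 0), y=(0, 0), z=(1, 1))
        plan = build_scan_plan(flat_surface, frame, bbox, "xy_at_depth", 1.0)
        assert len(plan) == 1
        body = [
            ln for ln in emit_gcode(plan).splitlines()
            if ln not in ("G21", "G90") and not ln.startswith("(sarscan")
        ]
        assert len(body) == 3
        assert body[0].startswith("G1 ")
        assert body[1] == "G4 P0.8"
        assert body[2] == "(READ n=3)"

    def test_empty_plan_rejected(self, flat_surface, frame):
        plan = ScanPlan(
            plane_kind="xy_at_depth",
            spacing=1.0,
            surface=flat_surface,
            frame=frame,
            surface_points=np.empty((0, 3)),
            points=[],
        )
        with pytest.raises(EmptyPlanError):
            emit_gcode(plan)

    def test_round_trip_preserves_points(self, flat_surface, frame, xy_bbox):
        plan = build_scan_plan(flat_surface, frame, xy_bbox, "xy_at_depth", 1.0)
        text = emit_gcode(plan)
        assert text.count("(READ n=3)") == 825
        points, dwell, n = parse_gcode(text)
        assert dwell == 0.8 and n == 3
        assert len(points) == len(plan)
        got = np.array([p.as_array() for p in points])
        want = np.array([p.as_array() for p in plan.points])
        assert np.allclose(got, want, atol=1e-9)
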