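"""Coordinate frames, contact-surface geometry, scan planning and motion programs.

Scans are planned in *surface coordinates* ``(u, v, depth)``: ``u`` is lateral
position along the (possibly curved) bolus--phantom contact surface measured as
arc length, ``v`` runs along the cylinder axis (the non-curved direction) and
``depth`` is the distance into the phantom below the contact surface.  For a
flat surface these reduce to the Cartesian axes of the measurement frame.

The measurement frame follows the IEC 61217 fixed reference system used in
radiotherapy QA, with the z axis re-signed so that z grows with depth into the
phantom.  Its origin is the centre of the applicator projected onto the
bolus--phantom interface; the robot frame origin is wherever the scanner's
homing switches put it, so a per-setup :class:`CoordinateFrame` translates
between the two.

All lengths are centimetres.  Millimetres appear only inside G-code text.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Point3",
    "CoordinateFrame",
    "ContactSurface",
    "BoundingBox",
    "ScanPlan",
    "DegenerateGeometryError",
    "OutOfWorkspaceError",
    "EmptyPlanError",
    "NegativeDepthError",
    "circle_from_three_points",
    "surface_from_three_points",
    "build_scan_plan",
    "emit_gcode",
    "parse_gcode",
]

#: half-aperture angle beyond which a cylindrical surface point is unreachable
_MAX_ARC_ANGLE = math.pi / 2

#: triangle area (cm^2) below which three circle points are declared collinear
COLLINEARITY_AREA_TOL = 1e-9


class DegenerateGeometryError(ValueError):
    """Raised when a geometric construction is ill-posed (e.g. collinear points)."""


class OutOfWorkspaceError(ValueError):
    """Raised when a requested point cannot be reached on the given surface."""


class EmptyPlanError(ValueError):
    """Raised when a scan plan would contain no measurement points."""


class NegativeDepthError(ValueError):
    """Raised for points above the contact surface (negative depth)."""


@dataclass(frozen=True)
class Point3:
    """A point in 3-space, cm."""

    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite coordinate {name}={getattr(self, name)!r}")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def distance_to(self, other: "Point3") -> float:
        return math.dist((self.x, self.y, self.z), (other.x, other.y, other.z))


@dataclass(frozen=True)
class CoordinateFrame:
    """Translation between robot and measurement coordinates.

    ``origin_in_robot`` is the applicator centre (at the bolus--phantom
    interface) expressed in robot coordinates.  With ``z_sign_flip`` the
    measurement z axis points into the phantom while the robot z axis points
    up, which is the common gantry-style convention.
    """

    origin_in_robot: Point3
    z_sign_flip: bool = True

    def to_measurement(self, p: Point3) -> Point3:
        o = self.origin_in_robot
        z = o.z - p.z if self.z_sign_flip else p.z - o.z
        return Point3(p.x - o.x, p.y - o.y, z)

    def to_robot(self, m: Point3) -> Point3:
        o = self.origin_in_robot
        z = o.z - m.z if self.z_sign_flip else m.z + o.z
        return Point3(m.x + o.x, m.y + o.y, z)


def circle_from_three_points(
    p1: Point3, p2: Point3, p3: Point3
) -> tuple[Point3, float]:
    """Circumcircle of three points projected onto the xz-plane.

    Used to recover the curvature of a bent applicator from three probe
    touch-points at the reference depth.  Returns ``(center, radius)`` with the
    centre's y component set to 0.

    Raises
    ------
    DegenerateGeometryError
        If the projected points are (nearly) collinear or coincident.
    """
    pts = [(p.x, p.z) for p in (p1, p2, p3)]
    (x1, z1), (x2, z2), (x3, z3) = pts
    area = 0.5 * abs((x2 - x1) * (z3 - z1) - (x3 - x1) * (z2 - z1))
    if area < COLLINEARITY_AREA_TOL:
        raise DegenerateGeometryError(
            f"collinear or duplicate points for circle fit: {pts}"
        )
    # perpendicular-bisector linear system: 2 (p_i - p_1) . c = |p_i|^2 - |p_1|^2
    a = np.array(
        [[2 * (x2 - x1), 2 * (z2 - z1)], [2 * (x3 - x1), 2 * (z3 - z1)]]
    )
    b = np.array(
        [x2**2 - x1**2 + z2**2 - z1**2, x3**2 - x1**2 + z3**2 - z1**2]
    )
    cx, cz = np.linalg.solve(a, b)
    radius = math.hypot(x1 - cx, z1 - cz)
    return Point3(float(cx), 0.0, float(cz)), float(radius)


@dataclass(frozen=True)
class ContactSurface:
    """Flat or cylindrical bolus--phantom contact surface.

    For ``kind="cylinder"`` the surface is a cylinder of radius ``radius``
    whose axis runs along y.  In the measurement frame the axis passes through
    ``(x=0, z=-radius)``: the applicator apex touches the origin and the
    centre of curvature sits above the phantom.  ``circle_center`` optionally
    records where the fitted circle centre was in robot coordinates.
    """

    kind: str = "flat"  # "flat" | "cylinder"
    radius: float | None = None
    circle_center: Point3 | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("flat", "cylinder"):
            raise ValueError(f"unknown surface kind {self.kind!r}")
        if self.kind == "cylinder":
            if self.radius is None or self.radius <= 0:
                raise ValueError("cylinder surface requires radius > 0")

    def surface_coordinates(self, p: Point3) -> tuple[float, float, float]:
        """Map a measurement-frame point to ``(u, v, depth)``.

        Raises :class:`NegativeDepthError` for points above the surface and
        :class:`OutOfWorkspaceError` for points beyond the cylinder's
        reachable half-aperture.
        """
        if self.kind == "flat":
            u, v, depth = p.x, p.y, p.z
        else:
            r = self.radius
            dx, dz = p.x, p.z + r
            dist = math.hypot(dx, dz)
            theta = math.atan2(dx, dz)
            if abs(theta) > _MAX_ARC_ANGLE + 1e-12:
                raise OutOfWorkspaceError(
                    f"point {p} beyond reachable half-aperture of r={r} cm cylinder"
                )
            u, v, depth = r * theta, p.y, dist - r
        if depth < -1e-9:
            raise NegativeDepthError(f"point {p} lies above the contact surface")
        return u, v, depth

    def point_at(self, u: float, v: float, depth: float) -> Point3:
        """Inverse of :meth:`surface_coordinates` (measurement frame)."""
        if depth < -1e-9:
            raise NegativeDepthError(f"negative depth {depth}")
        if self.kind == "flat":
            return Point3(u, v, depth)
        r = self.radius
        theta = u / r
        if abs(theta) > _MAX_ARC_ANGLE + 1e-12:
            raise OutOfWorkspaceError(
                f"arc length u={u} exceeds reachable half-aperture of r={r} cm cylinder"
            )
        rr = r + depth
        return Point3(rr * math.sin(theta), v, rr * math.cos(theta) - r)


def surface_from_three_points(
    p1: Point3, p2: Point3, p3: Point3, depth_reference: float = 1.0
) -> tuple[ContactSurface, Point3]:
    """Build a cylindrical surface from three probe points at the reference depth.

    The three points lie on the curve ``depth_reference`` below the contact
    surface, so the fitted circle radius exceeds the surface radius by that
    amount.  Returns the surface and the fitted circle centre (same frame as
    the inputs, normally robot coordinates).
    """
    center, fitted_radius = circle_from_three_points(p1, p2, p3)
    radius = fitted_radius - depth_reference
    if radius <= 0:
        raise DegenerateGeometryError(
            f"fitted radius {fitted_radius} cm does not exceed the "
            f"{depth_reference} cm reference depth"
        )
    return ContactSurface(kind="cylinder", radius=radius, circle_center=center), center


@dataclass(frozen=True)
class BoundingBox:
    """Scan limits, in surface coordinates: x↔u, y↔v, z↔depth (cm)."""

    x: tuple[float, float]
    y: tuple[float, float]
    z: tuple[float, float] = (1.0, 6.0)

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValueError(f"bounding box {name} interval {lo}..{hi} inverted")


@dataclass
class ScanPlan:
    """An ordered list of measurement points with motion parameters.

    ``surface_points`` is an ``(n, 3)`` array of ``(u, v, depth)`` triples in
    plan order; ``points`` holds the same sequence as robot-frame
    :class:`Point3`.
    """

    plane_kind: str  # "xy_at_depth" | "xz" | "yz" | "volume"
    spacing: float
    surface: ContactSurface
    frame: CoordinateFrame
    surface_points: np.ndarray
    points: list[Point3]
    depth_reference: float = 1.0
    dwell_s: float = 0.8
    n_readings: int = 3
    bbox: BoundingBox | None = None

    def __len__(self) -> int:
        return len(self.points)

    @property
    def measurement_points(self) -> list[Point3]:
        return [self.surface.point_at(u, v, d) for u, v, d in self.surface_points]


def _grid_axis(lo: float, hi: float, spacing: float) -> np.ndarray:
    """Grid nodes at integer multiples of ``spacing`` inside ``[lo, hi]``.

    Anchoring at multiples of the spacing keeps the measurement-frame origin on
    the grid, which makes coarse resamplings strict point subsets.
    """
    k0 = math.ceil(lo / spacing - 1e-9)
    k1 = math.floor(hi / spacing + 1e-9)
    return np.arange(k0, k1 + 1, dtype=float) * spacing


def _serpentine(rows: list[np.ndarray]) -> list[np.ndarray]:
    """Reverse every other row so consecutive rows join at the near end."""
    return [row if i % 2 == 0 else row[::-1] for i, row in enumerate(rows)]


def build_scan_plan(
    surface: ContactSurface,
    frame: CoordinateFrame,
    bbox: BoundingBox,
    plane_kind: str,
    spacing: float,
    depth_range: tuple[float, float] | None = None,
    depth_reference: float = 1.0,
    dwell_s: float = 0.8,
    n_readings: int = 3,
) -> ScanPlan:
    """Construct the ordered scan path for one plane or volume.

    The reference curve at ``depth_reference`` is emitted first, then the
    remaining bounding-box points row-major by increasing depth, serpentine
    within each row to minimise travel.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be positive, got {spacing}")
    if plane_kind not in ("xy_at_depth", "xz", "yz", "volume"):
        raise ValueError(f"unknown plane_kind {plane_kind!r}")
    if depth_range is None:
        depth_range = bbox.z
    d_lo, d_hi = depth_range
    if abs(d_lo - depth_reference) > 1e-9:
        raise ValueError(
            f"depth range must start at the {depth_reference} cm reference, got {d_lo}"
        )

    us = _grid_axis(bbox.x[0], bbox.x[1], spacing)
    vs = _grid_axis(bbox.y[0], bbox.y[1], spacing)
    n_deep = math.floor((d_hi - depth_reference) / spacing + 1e-9)
    depths = depth_reference + spacing * np.arange(n_deep + 1, dtype=float)

    triples: list[tuple[float, float, float]] = []
    if plane_kind == "xy_at_depth":
        if us.size == 0 or vs.size == 0:
            raise EmptyPlanError("spacing larger than bounding-box extent")
        rows = _serpentine([us for _ in vs])
        for v, row in zip(vs, rows):
            triples.extend((u, v, depth_reference) for u in row)
    elif plane_kind in ("xz", "yz"):
        lat = us if plane_kind == "xz" else vs
        if lat.size == 0 or depths.size == 0:
            raise EmptyPlanError("spacing larger than bounding-box extent")
        rows = _serpentine([lat for _ in depths])
        for d, row in zip(depths, rows):
            for q in row:
                triples.append((q, 0.0, d) if plane_kind == "xz" else (0.0, q, d))
    else:  # volume
        if us.size == 0 or vs.size == 0 or depths.size == 0:
            raise EmptyPlanError("spacing larger than bounding-box extent")
        for d in depths:
            rows = _serpentine([us for _ in vs])
            for v, row in zip(vs, rows):
                triples.extend((u, v, d) for u in row)

    surface_points = np.array(triples, dtype=float)
    # point_at raises OutOfWorkspaceError if the plan leaves the cylinder's reach
    points = [
        frame.to_robot(surface.point_at(u, v, d)) for u, v, d in surface_points
    ]
    return ScanPlan(
        plane_kind=plane_kind,
        spacing=spacing,
        surface=surface,
        frame=frame,
        surface_points=surface_points,
        points=points,
        depth_reference=depth_reference,
        dwell_s=dwell_s,
        n_readings=n_readings,
        bbox=bbox,
    )


# ---------------------------------------------------------------------------
# Motion program (G-code) text
# ---------------------------------------------------------------------------

_GCODE_MOVE = re.compile(
    r"^G1\s+X(?P<x>[-+0-9.eE]+)\s+Y(?P<y>[-+0-9.eE]+)\s+Z(?P<z>[-+0-9.eE]+)\s*$"
)
_GCODE_DWELL = re.compile(r"^G4\s+P(?P<p>[-+0-9.eE]+)\s*$")
_GCODE_READ = re.compile(r"^\(READ n=(?P<n>\d+)\)\s*$")


def emit_gcode(plan: ScanPlan) -> str:
    """Render a plan as metric, absolute G-code.

    One ``G1`` move per point (robot coordinates, cm converted to mm), each
    followed by a ``G4`` dwell for meter settling and a ``(READ n=...)``
    comment marker.  The runner script, not the file, triggers the voltage
    readings when it encounters the marker.
    """
    if len(plan) == 0:
        raise EmptyPlanError("cannot emit G-code for an empty plan")
    lines = [
        f"(sarscan plan plane={plan.plane_kind} spacing={plan.spacing:g}cm)",
        "G21",
        "G90",
    ]
    for p in plan.points:
        lines.append(
            "G1 X{} Y{} Z{}".format(
                format(p.x * 10.0, ".12g"),
                format(p.y * 10.0, ".12g"),
                format(p.z * 10.0, ".12g"),
            )
        )
        lines.append(f"G4 P{plan.dwell_s:g}")
        lines.append(f"(READ n={plan.n_readings})")
    return "\n".join(lines) + "\n"


def parse_gcode(text: str) -> tuple[list[Point3], float, int]:
    """Parse motion-program text back into ``(points_cm, dwell_s, n_readings)``."""
    points: list[Point3] = []
    dwell = 0.0
    n_readings = 0
    for line in text.splitlines():
        line = line.strip()
        if not line or line in ("G21", "G90"):
            continue
        m = _GCODE_MOVE.match(line)
        if m:
            points.append(
                Point3(
                    float(m["x"]) / 10.0, float(m["y"]) / 10.0, float(m["z"]) / 10.0
                )
            )
            continue
        m = _GCODE_DWELL.match(line)
        if m:
            dwell = float(m["p"])
            continue
        m = _GCODE_READ.match(line)
        if m:
            n_readings = int(m["n"])
            continue
        if line.startswith("("):  # other comments
            continue
        raise ValueError(f"unrecognised G-code line: {line!r}")
    return points, dwell, n_readings
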