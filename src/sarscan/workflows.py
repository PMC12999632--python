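"""The three QA studies and the routine-QA session pipeline.

Composes scan planning, the virtual applicator, calibration and the SAR
metrics into the reproducible studies a physicist would run when commissioning
an applicator: a spatial-resolution evaluation (how coarse may the scan grid
be before the field size drifts), a repeatability evaluation (between-day
variability of EFS, EPD and the positioning shifts over independent sessions)
and a characterization matrix over curvature and bolus-thickness conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration as cal
from . import metrics as met
from .geometry import BoundingBox, ContactSurface, CoordinateFrame, Point3, build_scan_plan
from .metrics import EPDResult, QAMetrics
from .records import ScanRecord
from .simulator import (
    ApplicatorModel,
    DiodeSensor,
    SessionNoise,
    VirtualSession,
)

__all__ = [
    "ResolutionStudyResult",
    "RepeatabilityResult",
    "CharacterizationReport",
    "default_frame",
    "default_surface",
    "default_bbox",
    "simulate_normalized_plane",
    "simulate_volume",
    "run_session_metrics",
    "resolution_study",
    "repeatability_study",
    "characterize_applicator",
    "axis_crossing_gate",
]

#: metrics aggregated in the repeatability table, in report order
REPEATABILITY_METRICS = ["efs_x", "efs_y", "dx", "dy", "epd_xz", "epd_yz"]


def default_frame() -> CoordinateFrame:
    """A virtual-robot frame: origin 20 cm up/along from the robot home."""
    return CoordinateFrame(origin_in_robot=Point3(25.0, 25.0, 20.0), z_sign_flip=True)


def default_surface(model: ApplicatorModel) -> ContactSurface:
    if model.curvature_radius is None:
        return ContactSurface(kind="flat")
    return ContactSurface(kind="cylinder", radius=model.curvature_radius)


def default_bbox(model: ApplicatorModel, plane_kind: str) -> BoundingBox:
    """Scan limits wide enough to contain the 50% contour with margin."""
    if plane_kind in ("xy_at_depth", "volume", "xz"):
        x = (-16.0, 16.0)
    else:
        x = (-1.0, 1.0)
    y = (-12.0, 12.0) if model.name == "5H" else (-14.0, 14.0)
    return BoundingBox(x=x, y=y, z=(1.0, 6.0))


def _plan(model, plane_kind, spacing, bbox=None, surface=None, frame=None):
    surface = surface if surface is not None else default_surface(model)
    frame = frame if frame is not None else default_frame()
    bbox = bbox if bbox is not None else default_bbox(model, plane_kind)
    return build_scan_plan(surface, frame, bbox, plane_kind, spacing)


def _normalized(session: VirtualSession, record: ScanRecord, curve) -> np.ndarray:
    ppv = cal.voltages_to_power(record, curve)
    return cal.normalize_relative_sar(ppv)


def _scan_and_normalize(session, model, plane_kind, spacing, power, bbox=None):
    plan = _plan(model, plane_kind, spacing, bbox=bbox)
    record = session.run_scan(plan, generator_power=power)
    curve = cal.fit_calibration(
        session.run_calibration_sweep(), session_id=session.session_id
    )
    pct = _normalized(session, record, curve)
    return record, pct


def simulate_normalized_plane(
    model: ApplicatorModel,
    plane_kind: str = "xy_at_depth",
    spacing: float = 1.0,
    power: float = 30.0,
    noise: SessionNoise | None = None,
    seed: int = 0,
    bbox: BoundingBox | None = None,
    sensor: DiodeSensor | None = None,
):
    """Full pipeline for one plane: sweep, fit, scan, convert, normalise.

    Returns ``(record, percent_values)`` with one value per scan point.
    """
    noise = noise if noise is not None else SessionNoise.none()
    session = VirtualSession(model, sensor=sensor, noise=noise, seed=seed)
    curve = cal.fit_calibration(
        session.run_calibration_sweep(), session_id=session.session_id
    )
    plan = _plan(model, plane_kind, spacing, bbox=bbox)
    record = session.run_scan(plan, generator_power=power)
    pct = cal.normalize_relative_sar(cal.voltages_to_power(record, curve))
    return record, pct


def simulate_volume(
    model: ApplicatorModel,
    spacing: float = 1.0,
    power: float = 30.0,
    noise: SessionNoise | None = None,
    seed: int = 0,
    bbox: BoundingBox | None = None,
) -> met.SARVolume:
    """Full-pipeline volume scan assembled into a dense SAR cube."""
    record, pct = simulate_normalized_plane(
        model, "volume", spacing, power, noise, seed, bbox
    )
    pts = record.data[["u", "v", "depth"]].to_numpy()
    return met.volume_from_scan(pts, pct)


# ---------------------------------------------------------------------------
# Spatial resolution study
# ---------------------------------------------------------------------------


@dataclass
class ResolutionStudyResult:
    reference_spacing: float
    table: pd.DataFrame  # spacing, efs_x, efs_y, diff_x_pct, diff_y_pct
    isolines: dict[float, met.IsolineSet]

    @property
    def max_rel_diff_pct(self) -> float:
        return float(
            self.table[["diff_x_pct", "diff_y_pct"]].abs().to_numpy().max()
        )


def resolution_study(
    points_uv: np.ndarray,
    values_pct: np.ndarray,
    source_spacing: float = 0.25,
    spacings: tuple[float, ...] = (1.0, 2.0, 4.0),
) -> ResolutionStudyResult:
    """Compare EFS across resamplings of one finely sampled plane.

    Each coarse subset (strict point subset, no interpolation) is
    independently interpolated to the 0.1 cm analysis grid before EFS
    computation; differences are reported relative to the fine reference.
    """
    rows = []
    isolines: dict[float, met.IsolineSet] = {}
    ref_grid = met.interpolate_plane(points_uv, values_pct)
    ref = met.compute_efs(ref_grid)
    isolines[source_spacing] = met.extract_isolines(ref_grid)
    rows.append((source_spacing, ref.efs_x, ref.efs_y, 0.0, 0.0))
    for s in spacings:
        if abs(s - source_spacing) < 1e-12:
            continue
        pts, vals = met.resample_plane(points_uv, values_pct, source_spacing, s)
        grid = met.interpolate_plane(pts, vals)
        efs = met.compute_efs(grid)
        isolines[s] = met.extract_isolines(grid)
        rows.append(
            (
                s,
                efs.efs_x,
                efs.efs_y,
                (efs.efs_x - ref.efs_x) / ref.efs_x * 100.0,
                (efs.efs_y - ref.efs_y) / ref.efs_y * 100.0,
            )
        )
    table = pd.DataFrame(
        rows, columns=["spacing_cm", "efs_x", "efs_y", "diff_x_pct", "diff_y_pct"]
    )
    return ResolutionStudyResult(
        reference_spacing=source_spacing, table=table, isolines=isolines
    )


# ---------------------------------------------------------------------------
# Repeatability study
# ---------------------------------------------------------------------------


@dataclass
class RepeatabilityResult:
    per_session: pd.DataFrame  # one row per session
    summary: pd.DataFrame  # metric, mean, sd, sd_pct
    excluded_sessions: list[int] = field(default_factory=list)


def run_session_metrics(
    model: ApplicatorModel,
    seed: int,
    sensor: DiodeSensor | None = None,
    noise: SessionNoise | None = None,
    power: float = 30.0,
    spacing: float = 1.0,
) -> QAMetrics:
    """One full simulated measurement day: calibration + xy/xz/yz scans."""
    noise = noise if noise is not None else SessionNoise()
    session = VirtualSession(model, sensor=sensor, noise=noise, seed=seed)
    curve = cal.fit_calibration(
        session.run_calibration_sweep(), session_id=session.session_id
    )

    def plane_pct(plane_kind):
        record = session.run_scan(_plan(model, plane_kind, spacing), power)
        return record, cal.normalize_relative_sar(
            cal.voltages_to_power(record, curve)
        )

    rec_xy, pct_xy = plane_pct("xy_at_depth")
    grid_xy = met.interpolate_plane(rec_xy.data[["u", "v"]].to_numpy(), pct_xy)
    efs = met.compute_efs(grid_xy)
    iso = met.extract_isolines(grid_xy)

    rec_xz, pct_xz = plane_pct("xz")
    grid_xz = met.interpolate_plane(
        rec_xz.data[["u", "depth"]].to_numpy(), pct_xz, axis_names=("u", "depth")
    )
    rec_yz, pct_yz = plane_pct("yz")
    grid_yz = met.interpolate_plane(
        rec_yz.data[["v", "depth"]].to_numpy(), pct_yz, axis_names=("v", "depth")
    )
    return QAMetrics(
        efs_x=efs.efs_x,
        efs_y=efs.efs_y,
        dx=efs.dx,
        dy=efs.dy,
        area_cm2=efs.area_cm2,
        epd_xz=met.compute_epd_from_plane(grid_xz),
        epd_yz=met.compute_epd_from_plane(grid_yz),
        isoline_components=iso.component_counts,
    )


def repeatability_study(
    model: ApplicatorModel,
    seeds=tuple(range(1, 9)),
    sensor: DiodeSensor | None = None,
    noise: SessionNoise | None = None,
    power: float = 30.0,
    spacing: float = 1.0,
) -> RepeatabilityResult:
    """Between-session variability of the QA metrics over independent sessions.

    Every session is a fully independent pipeline (fresh positioning offset,
    fresh calibration).  Sessions with a censored EPD are excluded from the
    aggregation and reported.  SD is the sample standard deviation (n - 1);
    SD% is SD over the absolute mean.
    """
    if len(seeds) < 2:
        raise ValueError("repeatability needs >= 2 sessions")
    rows, excluded = [], []
    for seed in seeds:
        m = run_session_metrics(model, seed, sensor, noise, power, spacing)
        if m.epd_xz.censored or m.epd_yz.censored:
            excluded.append(seed)
            continue
        rows.append(
            {
                "seed": seed,
                "efs_x": m.efs_x,
                "efs_y": m.efs_y,
                "dx": m.dx,
                "dy": m.dy,
                "epd_xz": m.epd_xz.value,
                "epd_yz": m.epd_yz.value,
            }
        )
    per_session = pd.DataFrame(rows)
    summary_rows = []
    for metric in REPEATABILITY_METRICS:
        vals = per_session[metric].to_numpy()
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        sd_pct = float("nan") if mean == 0 else sd / abs(mean) * 100.0
        summary_rows.append({"metric": metric, "mean": mean, "sd": sd, "sd_pct": sd_pct})
    return RepeatabilityResult(
        per_session=per_session,
        summary=pd.DataFrame(summary_rows).set_index("metric"),
        excluded_sessions=excluded,
    )


# ---------------------------------------------------------------------------
# Applicator characterization
# ---------------------------------------------------------------------------


def axis_crossing_gate(
    grid: met.RelativeSARGrid, level: float = 80.0, axis: str = "v"
) -> bool:
    """Does the central line (v=0 for the xz-plane, u=0 for yz) cross the
    >= ``level`` region of the xy grid?

    When it does, the EPD read off that central plane is a valid stand-in for
    the guideline EPD at the maximum-SAR position; when it does not, an extra
    scan positioned at the maximum is required.
    """
    region = (grid.values >= level) & grid.unmasked
    if axis == "v":
        on_line = np.abs(grid.v) <= met.GRID_SPACING / 2.0
        return bool(region[:, on_line].any())
    if axis == "u":
        on_line = np.abs(grid.u) <= met.GRID_SPACING / 2.0
        return bool(region[on_line, :].any())
    raise ValueError(f"axis must be 'u' or 'v', got {axis!r}")


@dataclass
class CharacterizationReport:
    summary: pd.DataFrame  # one row per scenario
    metrics: dict[str, QAMetrics]
    grids: dict[str, met.RelativeSARGrid]
    deltas: pd.DataFrame  # cross-scenario comparisons

    def to_markdown(self) -> str:
        lines = ["# Applicator characterization", "", self.summary.to_markdown()]
        if len(self.deltas):
            lines += ["", "## Cross-scenario deltas", "", self.deltas.to_markdown()]
        return "\n".join(lines) + "\n"


def characterize_applicator(
    models: dict[str, ApplicatorModel],
    sensor: DiodeSensor | None = None,
    noise: SessionNoise | None = None,
    power: float = 30.0,
    spacing: float = 1.0,
    seed_base: int = 0,
    axis_gate_level: float = 80.0,
) -> CharacterizationReport:
    """Measure xy- and xz-planes per scenario and compare metrics across them.

    Per scenario: one session (own calibration), EFS and centre shifts from
    the xy-plane, EPD from the xz-plane, isoline component counts, and the
    axis-crossing gate deciding whether the central-plane EPD is trustworthy.
    Cross-scenario deltas track EPD and EFS_x against curvature within each
    (applicator, bolus) group.
    """
    if not (80.0 <= axis_gate_level <= 90.0):
        raise ValueError("axis gate level must lie in [80, 90]")
    noise = noise if noise is not None else SessionNoise()
    rows = []
    all_metrics: dict[str, QAMetrics] = {}
    grids: dict[str, met.RelativeSARGrid] = {}
    for k, (name, model) in enumerate(models.items()):
        session = VirtualSession(
            model, sensor=sensor, noise=noise, seed=seed_base + k,
            session_id=f"charact-{name}-{seed_base + k}",
        )
        curve = cal.fit_calibration(
            session.run_calibration_sweep(), session_id=session.session_id
        )
        rec_xy = session.run_scan(_plan(model, "xy_at_depth", spacing), power)
        pct_xy = cal.normalize_relative_sar(cal.voltages_to_power(rec_xy, curve))
        grid_xy = met.interpolate_plane(rec_xy.data[["u", "v"]].to_numpy(), pct_xy)
        efs = met.compute_efs(grid_xy)
        iso = met.extract_isolines(grid_xy)

        rec_xz = session.run_scan(_plan(model, "xz", spacing), power)
        pct_xz = cal.normalize_relative_sar(cal.voltages_to_power(rec_xz, curve))
        grid_xz = met.interpolate_plane(
            rec_xz.data[["u", "depth"]].to_numpy(), pct_xz, axis_names=("u", "depth")
        )
        epd = met.compute_epd_from_plane(grid_xz)
        gate_ok = axis_crossing_gate(grid_xy, level=axis_gate_level, axis="v")

        all_metrics[name] = QAMetrics(
            efs_x=efs.efs_x,
            efs_y=efs.efs_y,
            dx=efs.dx,
            dy=efs.dy,
            area_cm2=efs.area_cm2,
            epd_xz=epd,
            isoline_components=iso.component_counts,
        )
        grids[name] = grid_xy
        rows.append(
            {
                "scenario": name,
                "applicator": model.name,
                "curvature_cm": model.curvature_radius,
                "bolus_cm": model.bolus_cm,
                "efs_x": efs.efs_x,
                "efs_y": efs.efs_y,
                "dx": efs.dx,
                "dy": efs.dy,
                "epd_xz": epd.value,
                "epd_censored": epd.censored,
                "n50_components": iso.component_counts[50.0],
                "axis_gate_ok": gate_ok,
                "session_id": session.session_id,
                "calibration_session": curve.session_id,
            }
        )
    summary = pd.DataFrame(rows).set_index("scenario")

    deltas = []
    for (app, bolus), grp in summary.groupby(["applicator", "bolus_cm"]):
        grp = grp.sort_values("curvature_cm", na_position="first")
        flat = grp[grp["curvature_cm"].isna()]
        if flat.empty:
            continue
        f = flat.iloc[0]
        for _, r in grp[grp["curvature_cm"].notna()].iterrows():
            deltas.append(
                {
                    "applicator": app,
                    "bolus_cm": bolus,
                    "curvature_cm": r["curvature_cm"],
                    "epd_minus_flat": r["epd_xz"] - f["epd_xz"],
                    "efs_x_minus_flat": r["efs_x"] - f["efs_x"],
                }
            )
    return CharacterizationReport(
        summary=summary,
        metrics=all_metrics,
        grids=grids,
        deltas=pd.DataFrame(deltas),
    )
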