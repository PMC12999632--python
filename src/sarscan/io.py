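"""File formats: scan CSVs with JSON sidecars, plan/curve JSON, run configs.

CSV dialect: comma separated, UTF-8, '.' decimal, mandatory header row.
Units are fixed (cm, V, W) and asserted through the sidecar metadata.  All
writes are atomic (temp file + rename) so a deterministic command re-run
overwrites byte-identically and a crash never leaves a half-written file.
"""

from __future__ import annotations

import io as _stdio
import json
import os
import tempfile
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, field_validator

from .calibration import CalibrationCurve
from .geometry import (
    BoundingBox,
    ContactSurface,
    CoordinateFrame,
    Point3,
    ScanPlan,
)
from .records import SCAN_COLUMNS, ScanRecord

__all__ = [
    "ScanFormatError",
    "RunConfig",
    "atomic_write_text",
    "write_json",
    "read_scan",
    "write_scan",
    "write_plan",
    "read_plan",
    "write_curve",
    "read_curve",
]

EXPECTED_UNITS = {"length": "cm", "voltage": "V", "power": "W"}


class ScanFormatError(ValueError):
    """A scan file (or its sidecar) does not match the declared format."""


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json(path, obj) -> None:
    atomic_write_text(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _sidecar(path) -> Path:
    return Path(path).with_suffix(".meta.json")


def write_scan(record: ScanRecord, path) -> None:
    """Write a scan record as CSV plus a ``<stem>.meta.json`` sidecar."""
    buf = _stdio.StringIO()
    record.data[SCAN_COLUMNS].to_csv(buf, index=False)
    atomic_write_text(path, buf.getvalue())
    meta = dict(record.metadata)
    meta.setdefault("units", EXPECTED_UNITS)
    write_json(_sidecar(path), meta)


def read_scan(path) -> ScanRecord:
    """Read a scan CSV and its sidecar; validates columns and units."""
    path = Path(path)
    if not path.exists():
        raise ScanFormatError(f"scan file not found: {path}")
    data = pd.read_csv(path)
    missing = [c for c in SCAN_COLUMNS if c not in data.columns]
    if missing:
        raise ScanFormatError(f"scan {path} missing columns: {missing}")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise ScanFormatError(f"missing metadata sidecar: {sidecar}")
    metadata = json.loads(sidecar.read_text())
    units = metadata.get("units", {})
    bad = {k: v for k, v in units.items() if EXPECTED_UNITS.get(k, v) != v}
    if bad:
        raise ScanFormatError(
            f"unit mismatch in {sidecar}: {bad} (expected {EXPECTED_UNITS})"
        )
    return ScanRecord(data=data, metadata=metadata)


# ---------------------------------------------------------------------------
# Scan plans
# ---------------------------------------------------------------------------


def _point_to_list(p: Point3) -> list[float]:
    return [p.x, p.y, p.z]


def write_plan(plan: ScanPlan, path) -> None:
    """Plan JSON: geometry, motion parameters and points in both frames."""
    surface = {"kind": plan.surface.kind}
    if plan.surface.kind == "cylinder":
        surface["radius"] = plan.surface.radius
        if plan.surface.circle_center is not None:
            surface["circle_center"] = _point_to_list(plan.surface.circle_center)
    obj = {
        "schema_version": 1,
        "plane_kind": plan.plane_kind,
        "spacing_cm": plan.spacing,
        "depth_reference_cm": plan.depth_reference,
        "dwell_s": plan.dwell_s,
        "n_readings": plan.n_readings,
        "surface": surface,
        "frame": {
            "origin_in_robot": _point_to_list(plan.frame.origin_in_robot),
            "z_sign_flip": plan.frame.z_sign_flip,
        },
        "points_robot": [_point_to_list(p) for p in plan.points],
        "points_surface": plan.surface_points.tolist(),
    }
    write_json(path, obj)


def read_plan(path) -> ScanPlan:
    import numpy as np

    obj = json.loads(Path(path).read_text())
    s = obj["surface"]
    surface = ContactSurface(
        kind=s["kind"],
        radius=s.get("radius"),
        circle_center=(
            Point3(*s["circle_center"]) if s.get("circle_center") else None
        ),
    )
    frame = CoordinateFrame(
        origin_in_robot=Point3(*obj["frame"]["origin_in_robot"]),
        z_sign_flip=obj["frame"]["z_sign_flip"],
    )
    return ScanPlan(
        plane_kind=obj["plane_kind"],
        spacing=obj["spacing_cm"],
        surface=surface,
        frame=frame,
        surface_points=np.asarray(obj["points_surface"], dtype=float),
        points=[Point3(*p) for p in obj["points_robot"]],
        depth_reference=obj["depth_reference_cm"],
        dwell_s=obj["dwell_s"],
        n_readings=obj["n_readings"],
    )


# ---------------------------------------------------------------------------
# Calibration curves
# ---------------------------------------------------------------------------


def write_curve(curve: CalibrationCurve, path) -> None:
    write_json(
        path,
        {
            "schema_version": 1,
            "A_W_per_V2": curve.a,
            "B_W_per_V": curve.b,
            "C_W": curve.c,
            "r_squared": curve.r_squared,
            "v_range_V": list(curve.v_range),
            "session_id": curve.session_id,
        },
    )


def read_curve(path) -> CalibrationCurve:
    obj = json.loads(Path(path).read_text())
    return CalibrationCurve(
        a=obj["A_W_per_V2"],
        b=obj["B_W_per_V"],
        c=obj["C_W"],
        r_squared=obj["r_squared"],
        v_range=tuple(obj["v_range_V"]),
        session_id=obj.get("session_id"),
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


class RunConfig(BaseModel):
    """Validated QA-run configuration (YAML); unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    schema_version: int = 1
    scenario: str = "5H-flat-1.3"
    planes: list[str] = ["xy_at_depth", "xz", "yz"]
    spacing_cm: float = 1.0
    power_w: float = 30.0
    seed: int = 0
    epd_convention: str = "additional"  # or "from_interface"
    axis_gate_pct: float = 80.0

    @field_validator("spacing_cm", "power_w")
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @field_validator("epd_convention")
    @classmethod
    def _convention(cls, v):
        if v not in ("additional", "from_interface"):
            raise ValueError("epd_convention must be 'additional' or 'from_interface'")
        return v

    @field_validator("axis_gate_pct")
    @classmethod
    def _gate(cls, v):
        if not (80.0 <= v <= 90.0):
            raise ValueError("axis_gate_pct must lie in [80, 90]")
        return v

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))
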