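"""Diode-sensor calibration and voltage-to-relative-SAR conversion.

The sensor response is calibrated against generated power with a quadratic
``P = A V^2 + B V + C``; because SAR is proportional to |E|^2 and hence to the
applied power, applying the fitted quadratic to scan voltages yields values
proportional to SAR.  Normalising each scan to the maximum at the 1 cm
reference depth (= 100%) then gives relative SAR, which is all the QA metrics
need -- the procedure is deliberately relative, no W/kg is ever claimed.

The quadratic is linear in its coefficients, so the fit is ordinary least
squares even though the response itself is nonlinear in V.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import ScanRecord

__all__ = [
    "CalibrationCurve",
    "PowerProportionalValues",
    "CalibrationError",
    "SessionMismatchError",
    "ExtrapolationError",
    "DegenerateScanError",
    "CoverageWarning",
    "fit_calibration",
    "voltages_to_power",
    "normalize_relative_sar",
]


class CalibrationError(ValueError):
    """Calibration fit invalid (non-monotone curve, rank-deficient design...)."""


class SessionMismatchError(ValueError):
    """A scan was paired with a calibration from a different session."""


class ExtrapolationError(ValueError):
    """Scan voltages far beyond the calibrated range."""


class DegenerateScanError(ValueError):
    """Scan values unusable (e.g. all zero) for normalisation."""


class CoverageWarning(UserWarning):
    """Calibration sweep does not cover the scan's voltage range."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted quadratic voltage-to-power response for one session."""

    a: float  # W / V^2
    b: float  # W / V
    c: float  # W
    r_squared: float
    v_range: tuple[float, float]  # voltages covered by the sweep
    session_id: str | None = None

    def __call__(self, v):
        v = np.asarray(v, dtype=float)
        return self.a * v**2 + self.b * v + self.c


@dataclass
class PowerProportionalValues:
    """Per-point power-equivalent values derived from one scan."""

    values: np.ndarray  # W-equivalent, >= 0
    n_clipped: int  # negatives clipped to 0 (diode floor)
    record: ScanRecord | None = None


def fit_calibration(
    sweep: pd.DataFrame, session_id: str | None = None
) -> CalibrationCurve:
    """Least-squares quadratic fit of power against measured voltage.

    ``sweep`` needs columns ``power_W`` and ``v_out`` with at least four
    distinct voltages.  The fitted curve must be strictly increasing over the
    sweep's voltage range, otherwise the diode inversion would be ambiguous
    and the calibration is rejected.
    """
    for col in ("power_W", "v_out"):
        if col not in sweep.columns:
            raise CalibrationError(f"sweep missing column {col!r}")
    v = np.asarray(sweep["v_out"], dtype=float)
    p = np.asarray(sweep["power_W"], dtype=float)
    if np.unique(v).size < 4:
        raise CalibrationError(
            f"need >= 4 distinct sweep points, got {np.unique(v).size}"
        )
    design = np.column_stack([v**2, v, np.ones_like(v)])
    if np.linalg.matrix_rank(design) < 3:
        raise CalibrationError("rank-deficient design matrix")
    coef, *_ = np.linalg.lstsq(design, p, rcond=None)
    a, b, c = (float(x) for x in coef)
    fitted = design @ coef
    ss_res = float(np.sum((p - fitted) ** 2))
    ss_tot = float(np.sum((p - p.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    v_lo, v_hi = float(v.min()), float(v.max())
    # derivative 2 a v + b must stay positive on the data range
    if min(2 * a * v_lo + b, 2 * a * v_hi + b) <= 0:
        raise CalibrationError(
            "fitted curve is not monotonically increasing on the sweep range"
        )
    return CalibrationCurve(
        a=a, b=b, c=c, r_squared=r2, v_range=(v_lo, v_hi), session_id=session_id
    )


def check_coverage(curve: CalibrationCurve, scan_voltages) -> bool:
    """Warn when the sweep covers < 90% of a scan's voltage span."""
    sv = np.asarray(scan_voltages, dtype=float)
    scan_span = float(sv.max() - sv.min())
    cal_span = curve.v_range[1] - curve.v_range[0]
    covered = scan_span <= 0 or cal_span >= 0.9 * scan_span
    if not covered:
        warnings.warn(
            f"calibration voltage span {cal_span:.3g} V covers less than 90% of "
            f"the scan span {scan_span:.3g} V",
            CoverageWarning,
            stacklevel=2,
        )
    return covered


def voltages_to_power(
    record: ScanRecord,
    curve: CalibrationCurve,
    allow_session_mismatch: bool = False,
) -> PowerProportionalValues:
    """Apply the calibration quadratic to a scan's mean voltages.

    Refuses to mix sessions (a fresh calibration is made every measurement
    day) unless explicitly overridden.  Small negatives from noise near V=0
    are clipped to the diode floor at 0 and counted; voltages more than 10%
    beyond the calibrated maximum abort with an extrapolation error, which
    almost always signals a wrong calibration file.
    """
    if (
        not allow_session_mismatch
        and record.session_id is not None
        and curve.session_id is not None
        and record.session_id != curve.session_id
    ):
        raise SessionMismatchError(
            f"scan session {record.session_id!r} != calibration session "
            f"{curve.session_id!r}; pass allow_session_mismatch=True to override"
        )
    v = np.asarray(record.data["v_mean"], dtype=float)
    if float(v.max()) > curve.v_range[1] * 1.1:
        raise ExtrapolationError(
            f"scan voltage {v.max():.3g} V exceeds calibrated maximum "
            f"{curve.v_range[1]:.3g} V by more than 10%"
        )
    check_coverage(curve, v)
    values = curve(v)
    n_clipped = int(np.sum(values < 0))
    return PowerProportionalValues(
        values=np.clip(values, 0.0, None), n_clipped=n_clipped, record=record
    )


def normalize_relative_sar(
    ppv: PowerProportionalValues,
    depth_reference: float = 1.0,
    reference_rule: str = "depth-max",
) -> np.ndarray:
    """Normalise power-proportional values to percent of the reference maximum.

    ``depth-max`` (the default) anchors at the maximum value among points at
    the reference depth (within half a grid spacing), per-scan; ``plane-max``
    uses the global maximum instead, for sensitivity checks.  Values above
    100% are possible with ``depth-max`` when a deeper point exceeds every
    reference-depth point; that is reported with a warning, not an error.
    """
    if ppv.record is None:
        raise ValueError("normalisation requires the source scan record")
    values = ppv.values
    if float(values.max()) <= 0:
        raise DegenerateScanError("all power-proportional values are zero")
    if reference_rule == "plane-max":
        reference = float(values.max())
    elif reference_rule == "depth-max":
        depth = np.asarray(ppv.record.data["depth"], dtype=float)
        spacing = ppv.record.spacing or 1.0
        at_ref = np.abs(depth - depth_reference) <= spacing / 2.0 + 1e-9
        if not at_ref.any():
            raise DegenerateScanError(
                f"no points at the {depth_reference} cm reference depth"
            )
        reference = float(values[at_ref].max())
        if reference <= 0:
            raise DegenerateScanError("reference-depth values are all zero")
        if float(values.max()) > reference * (1 + 1e-9):
            warnings.warn(
                "a point below the reference depth exceeds the reference "
                "maximum; normalized values above 100% will be emitted",
                UserWarning,
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown reference rule {reference_rule!r}")
    return 100.0 * values / reference
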