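"""Virtual applicator: a parametric stand-in for robot, phantom and sensor.

The simulator replaces the physical scanner so every stage of the QA pipeline
-- calibration sweeps, plane and volume scans, repeatability sessions -- runs
at desk scale.  The relative-SAR field is an explicit parametric model, not an
electromagnetic solution: a separable Gaussian aperture profile with
exponential power decay in depth, made non-separable through depth-dependent
lateral broadening, optionally modulated by a cosine ripple that mimics the
isoline splitting seen under excessively thick water boluses.

Default presets for the two contact flexible microstrip applicator (CFMA)
geometries are tuned so a noiseless pipeline run reproduces the published
summary metrics (effective field size and effective penetration depth) of the
corresponding physical applicators; see ``docs/methods.md``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .geometry import ScanPlan
from .records import ScanRecord

__all__ = [
    "PhantomProperties",
    "ApplicatorModel",
    "DiodeSensor",
    "SessionNoise",
    "VirtualSession",
    "SensorRangeError",
    "CalibrationPointError",
    "FWHM_FACTOR",
    "applicator_preset",
    "scenario",
    "builtin_scenarios",
    "load_scenarios",
    "run_virtual_scan",
    "run_calibration_sweep",
]

#: full width at half maximum of a unit Gaussian, 2*sqrt(2 ln 2)
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


class SensorRangeError(ValueError):
    """Equivalent power outside the sensor's invertible response range."""


class CalibrationPointError(ValueError):
    """Calibration sweep requested at a point without high relative SAR."""


@dataclass(frozen=True)
class PhantomProperties:
    """Saline phantom electrical properties (434 MHz, ~21 degC defaults)."""

    conductivity: float = 0.53  # S/m
    permittivity: float = 78.7  # relative
    density: float = 1000.0  # kg/m^3
    salinity: float = 3.0  # g/L NaCl

    def __post_init__(self) -> None:
        if self.conductivity <= 0 or self.density <= 0:
            raise ValueError("conductivity and density must be positive")


@dataclass(frozen=True)
class ApplicatorModel:
    """Parametric CFMA-like relative-SAR field.

    The field at surface coordinates ``(u, v)`` and depth ``d`` (cm) is::

        exp(-(u-cx)^2 / 2 sx(d)^2) * exp(-(v-cy)^2 / 2 sy(d)^2)
            * exp(-2 (d - 1) / delta)

    with ``s(d) = s0 * (1 + kappa * (d - 1))``.  ``kappa > 0`` broadens the
    lateral profile with depth, which makes the field non-separable: columns
    away from the field centre decay more slowly, so the penetration depth
    varies across the aperture.  ``ripple_amplitude > 0`` multiplies the field
    by ``1 + m cos(2 pi u / L) cos(2 pi v / L)``, splitting high isolines the
    way resonance effects under a thick bolus do.  Curvature couples weakly:
    the depth constant grows and the along-curvature width shrinks with 1/r.
    """

    name: str = "5H"
    aperture_x: float = 19.7  # cm
    aperture_y: float = 28.5  # cm
    sigma_x0: float = 8.8755  # cm, lateral width along x at 1 cm depth
    sigma_y0: float = 5.3083  # cm
    delta: float = 7.9062  # cm, power-decay depth constant
    kappa: float = 0.03  # 1/cm, lateral broadening per cm depth
    centre_offset: tuple[float, float] = (0.8, -0.9)  # cm, true field centre
    curvature_radius: float | None = None  # cm, None = flat
    bolus_cm: float = 1.3
    ripple_amplitude: float = 0.0  # dimensionless, in [0, 1)
    ripple_period: float = 9.0  # cm
    epd_curvature_gain: float = 1.0  # cm: delta factor 1 + gain/r
    efs_curvature_shrink: float = 2.0  # cm: sigma_x factor 1 - shrink/r

    def __post_init__(self) -> None:
        if min(self.sigma_x0, self.sigma_y0, self.delta, self.ripple_period) <= 0:
            raise ValueError("widths, depth constant and ripple period must be > 0")
        if not (0.0 <= self.ripple_amplitude < 1.0):
            raise ValueError("ripple amplitude must be in [0, 1)")

    @property
    def _curvature(self) -> float:
        return 0.0 if self.curvature_radius is None else 1.0 / self.curvature_radius

    @property
    def sigma_x_eff(self) -> float:
        return self.sigma_x0 * (1.0 - self.efs_curvature_shrink * self._curvature)

    @property
    def delta_eff(self) -> float:
        return self.delta * (1.0 + self.epd_curvature_gain * self._curvature)

    def relative_sar(self, u, v, depth):
        """Dimensionless relative SAR (1 at the field centre at 1 cm depth)."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        depth = np.asarray(depth, dtype=float)
        cx, cy = self.centre_offset
        grow = 1.0 + self.kappa * (depth - 1.0)
        sx = self.sigma_x_eff * grow
        sy = self.sigma_y0 * grow
        val = (
            np.exp(-((u - cx) ** 2) / (2.0 * sx**2))
            * np.exp(-((v - cy) ** 2) / (2.0 * sy**2))
            * np.exp(-2.0 * (depth - 1.0) / self.delta_eff)
        )
        if self.ripple_amplitude > 0.0:
            two_pi = 2.0 * math.pi / self.ripple_period
            val = val * (
                1.0
                + self.ripple_amplitude * np.cos(two_pi * u) * np.cos(two_pi * v)
            )
        return val


@dataclass(frozen=True)
class DiodeSensor:
    """Diode-dipole E-field sensor with a quadratic power response.

    The forward response is ``P = A V^2 + B V + C`` with A, B, C the *true*
    coefficients the calibration procedure tries to recover; it never sees
    them directly.  Strict monotonicity on the valid voltage range makes the
    inversion (power to voltage) unique via the positive root.
    """

    a: float = 0.02  # W / V^2
    b: float = 0.5  # W / V
    c: float = 0.0  # W
    v_range: tuple[float, float] = (0.0, 60.0)

    def __post_init__(self) -> None:
        lo, hi = self.v_range
        if not (lo < hi):
            raise ValueError("invalid voltage range")
        if 2.0 * self.a * lo + self.b <= 0 or 2.0 * self.a * hi + self.b <= 0:
            raise ValueError("response not strictly increasing on the valid range")

    def power_for_voltage(self, v):
        v = np.asarray(v, dtype=float)
        return self.a * v**2 + self.b * v + self.c

    def voltage_for_power(self, p):
        """Positive root of the quadratic; raises for unreachable powers."""
        p = np.asarray(p, dtype=float)
        if np.any(p < self.c - 1e-12):
            raise SensorRangeError("equivalent power below the sensor floor C")
        if self.a == 0.0:
            v = (p - self.c) / self.b
        else:
            disc = self.b**2 - 4.0 * self.a * (self.c - p)
            v = (-self.b + np.sqrt(disc)) / (2.0 * self.a)
        if np.any(v > self.v_range[1] + 1e-12) or np.any(v < self.v_range[0] - 1e-12):
            raise SensorRangeError("voltage outside the sensor's valid range")
        return v


@dataclass(frozen=True)
class SessionNoise:
    """Per-session and per-reading noise model.

    One positioning offset per session (applicator/sensor alignment is done
    visually once per day), multiplicative noise on every voltage reading.
    """

    positioning_sd: float = 0.5  # cm per axis
    reading_sd: float = 0.004  # fraction of the reading

    def __post_init__(self) -> None:
        if self.positioning_sd < 0 or self.reading_sd < 0:
            raise ValueError("noise SDs must be non-negative")

    @staticmethod
    def none() -> "SessionNoise":
        return SessionNoise(positioning_sd=0.0, reading_sd=0.0)


class VirtualSession:
    """One simulated measurement day: a drawn setup offset plus seeded noise.

    All randomness comes from a single generator seeded at construction; the
    positioning offset is drawn once, so every scan and sweep in the session
    shares the same misalignment, as in the physical procedure.
    """

    def __init__(
        self,
        model: ApplicatorModel,
        sensor: DiodeSensor | None = None,
        noise: SessionNoise | None = None,
        seed: int = 0,
        phantom: PhantomProperties | None = None,
        session_id: str | None = None,
    ) -> None:
        self.model = model
        self.sensor = sensor if sensor is not None else DiodeSensor()
        self.noise = noise if noise is not None else SessionNoise()
        self.phantom = phantom if phantom is not None else PhantomProperties()
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        if self.noise.positioning_sd > 0:
            self.offset = self.rng.normal(0.0, self.noise.positioning_sd, size=2)
        else:
            self.offset = np.zeros(2)
        self.session_id = session_id or f"session-{self.seed}"

    # -- internals ----------------------------------------------------------
    def _triplicate(self, v0: np.ndarray, n: int = 3) -> np.ndarray:
        v0 = np.atleast_1d(np.asarray(v0, dtype=float))
        if self.noise.reading_sd > 0:
            eps = self.rng.normal(0.0, self.noise.reading_sd, size=(v0.size, n))
        else:
            eps = np.zeros((v0.size, n))
        return v0[:, None] * (1.0 + eps)

    def _relative_sar_at(self, u, v, depth):
        """Field as sampled by the misaligned setup: the true centre is shifted
        by the session offset relative to the visually aligned origin."""
        ox, oy = self.offset
        return self.model.relative_sar(
            np.asarray(u, float) - ox, np.asarray(v, float) - oy, depth
        )

    # -- operations ---------------------------------------------------------
    def virtual_reading(
        self, u: float, v: float, depth: float, generator_power: float
    ) -> tuple[float, float, float, float]:
        """Triplicate voltage reading at one surface-coordinate position."""
        if generator_power < 0:
            raise ValueError("generator power must be non-negative")
        p_eq = generator_power * self._relative_sar_at(u, v, depth)
        v0 = self.sensor.voltage_for_power(p_eq)
        trip = self._triplicate(v0)[0]
        return float(trip[0]), float(trip[1]), float(trip[2]), float(trip.mean())

    def run_scan(self, plan: ScanPlan, generator_power: float = 30.0) -> ScanRecord:
        """Execute a plan: one triplicate reading per point, in plan order."""
        if len(plan) == 0:
            raise ValueError("cannot scan an empty plan")
        uvd = plan.surface_points
        rs = self._relative_sar_at(uvd[:, 0], uvd[:, 1], uvd[:, 2])
        try:
            v0 = self.sensor.voltage_for_power(generator_power * rs)
        except SensorRangeError as exc:
            bad = int(
                np.argmax(generator_power * rs > self.sensor.power_for_voltage(
                    self.sensor.v_range[1]))
            )
            raise SensorRangeError(f"{exc} (first offending point index {bad})")
        trips = self._triplicate(v0, plan.n_readings)
        meas = np.array([p.as_array() for p in plan.measurement_points])
        robot = np.array([p.as_array() for p in plan.points])
        data = pd.DataFrame(
            {
                "x_robot": robot[:, 0],
                "y_robot": robot[:, 1],
                "z_robot": robot[:, 2],
                "x_meas": meas[:, 0],
                "y_meas": meas[:, 1],
                "z_meas": meas[:, 2],
                "u": uvd[:, 0],
                "v": uvd[:, 1],
                "depth": uvd[:, 2],
                "v1": trips[:, 0],
                "v2": trips[:, 1],
                "v3": trips[:, 2],
                "v_mean": trips.mean(axis=1),
            }
        )
        metadata = {
            "schema_version": 1,
            "power_W": float(generator_power),
            "conductivity_S_per_m": self.phantom.conductivity,
            "permittivity": self.phantom.permittivity,
            "salinity_g_per_L": self.phantom.salinity,
            "applicator": self.model.name,
            "bolus_cm": self.model.bolus_cm,
            "curvature_cm": self.model.curvature_radius,
            "seed": self.seed,
            "session_id": self.session_id,
            "plane_kind": plan.plane_kind,
            "spacing_cm": plan.spacing,
            "depth_reference_cm": plan.depth_reference,
            "units": {"length": "cm", "voltage": "V", "power": "W"},
        }
        return ScanRecord(data=data, metadata=metadata)

    def plane_max_relative_sar(self, depth: float = 1.0) -> float:
        """Coarse estimate of the maximum relative SAR on the given depth layer."""
        half_x = self.model.aperture_x / 2.0 + 2.0
        half_y = self.model.aperture_y / 2.0 + 2.0
        uu, vv = np.meshgrid(
            np.linspace(-half_x, half_x, 121), np.linspace(-half_y, half_y, 121)
        )
        return float(self._relative_sar_at(uu, vv, depth).max())

    def run_calibration_sweep(
        self,
        powers=tuple(float(p) for p in range(0, 55, 5)),
        point: tuple[float, float] | None = None,
        depth: float = 1.0,
    ) -> pd.DataFrame:
        """Sweep generator power at a fixed high-SAR point, recording v_mean.

        Default point: the field maximum as the operator locates it relative
        to the (offset) applicator, so the sensor sits where relative SAR = 1
        and the sweep covers the full voltage range of subsequent scans.
        """
        cx, cy = self.model.centre_offset
        if point is None:
            point = (cx + self.offset[0], cy + self.offset[1])
        rs = float(self._relative_sar_at(point[0], point[1], depth))
        if rs < 0.9 * self.plane_max_relative_sar(depth):
            raise CalibrationPointError(
                f"calibration point {point} has relative SAR {rs:.3f}, "
                "below 90% of the plane maximum"
            )
        rows = []
        for p in powers:
            v0 = self.sensor.voltage_for_power(p * rs)
            rows.append((float(p), float(self._triplicate(v0).mean())))
        return pd.DataFrame(rows, columns=["power_W", "v_out"])


def run_virtual_scan(
    plan: ScanPlan,
    model: ApplicatorModel,
    sensor: DiodeSensor | None = None,
    noise: SessionNoise | None = None,
    generator_power: float = 30.0,
    seed: int = 0,
) -> ScanRecord:
    """One-shot scan: draws a fresh session (one positioning offset) and runs."""
    return VirtualSession(model, sensor, noise, seed=seed).run_scan(
        plan, generator_power
    )


def run_calibration_sweep(
    model: ApplicatorModel,
    sensor: DiodeSensor | None = None,
    noise: SessionNoise | None = None,
    powers=tuple(float(p) for p in range(0, 55, 5)),
    point: tuple[float, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One-shot calibration sweep in a fresh session."""
    return VirtualSession(model, sensor, noise, seed=seed).run_calibration_sweep(
        powers, point=point
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

# Published summary metrics the default fields are tuned to (flat, 1.3 cm bolus):
# EFS_x x EFS_y at 1 cm depth and EPD (additional depth beyond 1 cm).
_APPLICATOR_TARGETS = {
    "3H": {"aperture": (28.7, 20.8), "efs": (15.2, 20.4), "epd": 2.74},
    "5H": {"aperture": (19.7, 28.5), "efs": (20.9, 12.5), "epd": 2.74},
}

#: thick-bolus ripple defaults: splits the 50% isoline region
_THICK_BOLUS_RIPPLE = {"ripple_amplitude": 0.35, "ripple_period": 9.0}


def applicator_preset(
    name: str = "5H",
    curvature_radius: float | None = None,
    bolus_cm: float = 1.3,
    **overrides,
) -> ApplicatorModel:
    """Build an :class:`ApplicatorModel` for a named CFMA geometry.

    Lateral widths come from the published field sizes via the Gaussian FWHM
    relation ``sigma = EFS / (2 sqrt(2 ln 2))`` and the depth constant from the
    exponential EPD closed form ``delta = 2 EPD / ln 2`` (both exact at the
    field-centre column, where the broadening term cancels).  A bolus of 2 cm
    or more switches on the ripple mode.
    """
    try:
        t = _APPLICATOR_TARGETS[name]
    except KeyError:
        raise KeyError(
            f"unknown applicator {name!r}; choose from {sorted(_APPLICATOR_TARGETS)}"
        )
    params = dict(
        name=name,
        aperture_x=t["aperture"][0],
        aperture_y=t["aperture"][1],
        sigma_x0=t["efs"][0] / FWHM_FACTOR,
        sigma_y0=t["efs"][1] / FWHM_FACTOR,
        delta=2.0 * t["epd"] / math.log(2.0),
        curvature_radius=curvature_radius,
        bolus_cm=bolus_cm,
    )
    if bolus_cm >= 2.0:
        params.update(_THICK_BOLUS_RIPPLE)
    params.update(overrides)
    return ApplicatorModel(**params)


def scenario(name: str) -> ApplicatorModel:
    """Resolve a scenario id like ``5H-flat-1.3`` or ``3H-r17.5-2.5``."""
    try:
        app, surf, bolus = name.split("-")
        bolus_cm = float(bolus)
        if surf == "flat":
            radius = None
        elif surf.startswith("r"):
            radius = float(surf[1:])
        else:
            raise ValueError
    except ValueError:
        raise ValueError(
            f"cannot parse scenario {name!r}; expected "
            "'<applicator>-<flat|r<radius>>-<bolus_cm>'"
        )
    return applicator_preset(app, curvature_radius=radius, bolus_cm=bolus_cm)


def builtin_scenarios() -> list[str]:
    """Scenario ids covering the characterization matrix."""
    out = []
    for app in ("3H", "5H"):
        for surf in ("flat", "r28", "r17.5"):
            for bolus in ("1.3", "2.5"):
                out.append(f"{app}-{surf}-{bolus}")
    return out


def load_scenarios(path) -> dict[str, ApplicatorModel]:
    """Load scenario presets from a YAML mapping of id -> parameter overrides.

    Each entry may give ``applicator``, ``curvature_radius`` and ``bolus_cm``
    plus any :class:`ApplicatorModel` field override; a bare ``null`` entry
    resolves the id itself through :func:`scenario`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, ApplicatorModel] = {}
    for key, spec_ in raw.items():
        if spec_ is None:
            out[key] = scenario(key)
            continue
        spec_ = dict(spec_)
        app = spec_.pop("applicator", key.split("-")[0])
        radius = spec_.pop("curvature_radius", None)
        bolus = spec_.pop("bolus_cm", 1.3)
        out[key] = applicator_preset(
            app, curvature_radius=radius, bolus_cm=bolus, **spec_
        )
    return out
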