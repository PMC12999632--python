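"""Grid interpolation, isoline extraction and the SAR QA metrics.

Metrics follow the hyperthermia QA guideline definitions: the effective field
size (EFS) is the extent of the region above 50% of the maximum relative SAR
in the plane 1 cm below the bolus--phantom interface, reported as extents
along the applicator's main axes; the effective penetration depth (EPD) is
the additional depth at which the SAR falls to 50% of its value at 1 cm
depth, evaluated at (or near) the maximum-SAR position.  The DeltaEPD map
quantifies how much the EPD at an arbitrary aperture position deviates from
the EPD at the maximum-SAR position,

    DeltaEPD(x, y) = (EPD(x, y) - EPD(maxSAR)) / EPD(maxSAR) * 100%,

which is what justifies (or forbids) reading the EPD off the central planes
instead of re-positioning the scan at the maximum.

Scattered measurement points are linearly interpolated (Delaunay-based) onto
a 0.1 x 0.1 cm grid before contouring; cells outside the measured convex hull
are masked and never contribute to maxima, contours or extents.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import griddata
from skimage import measure

__all__ = [
    "GRID_SPACING",
    "RelativeSARGrid",
    "SARVolume",
    "IsolineSet",
    "EFSResult",
    "EPDResult",
    "QAMetrics",
    "DeltaEPDMap",
    "TruncationWarning",
    "VolumeTooShallowError",
    "interpolate_plane",
    "linear_interpolate",
    "extract_isolines",
    "compute_efs",
    "compute_epd_from_plane",
    "compute_delta_epd",
    "resample_plane",
    "epd_difference_at_threshold",
    "volume_from_scan",
]

#: analysis grid spacing, cm
GRID_SPACING = 0.1


class TruncationWarning(UserWarning):
    """The 50% region touches the measured boundary: the scan box is too small."""


class VolumeTooShallowError(ValueError):
    """EPD at the max-SAR column is censored: the volume does not reach 50%."""


@dataclass
class RelativeSARGrid:
    """Normalised SAR on a regular 0.1 cm plane grid.

    ``values[i, j]`` is the percent SAR at ``(u[i], v[j])``; ``mask`` is True
    outside the measured convex hull.  ``axis_names`` distinguishes aperture
    planes ``("u", "v")`` from depth planes ``("u", "depth")`` /
    ``("v", "depth")``.
    """

    u: np.ndarray
    v: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    axis_names: tuple[str, str] = ("u", "v")
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ax in (self.u, self.v):
            if ax.size > 1 and not np.allclose(np.diff(ax), GRID_SPACING):
                raise ValueError(f"grid spacing must be {GRID_SPACING} cm")
        if self.values.shape != (self.u.size, self.v.size):
            raise ValueError("values shape does not match axes")

    @property
    def unmasked(self) -> np.ndarray:
        return ~self.mask


@dataclass
class SARVolume:
    """Normalised SAR on the measurement grid of a volume scan.

    ``values[i, j, k]`` at ``(u[i], v[j], depth[k])``; the depth axis starts
    at the 1 cm reference and keeps the measurement spacing (no depth
    interpolation happens before per-column EPD extraction).
    """

    u: np.ndarray
    v: np.ndarray
    depth: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (self.u.size, self.v.size, self.depth.size):
            raise ValueError("values shape does not match axes")
        if abs(self.depth[0] - 1.0) > 1e-6:
            raise ValueError("depth axis must start at the 1 cm reference")


@dataclass
class IsolineSet:
    """Marching-squares contours per level with connected-component counts."""

    levels: tuple[float, ...]
    contours: dict[float, list[np.ndarray]]  # level -> list of (n, 2) polylines
    component_counts: dict[float, int]  # connected components of cells >= level


@dataclass
class EFSResult:
    efs_x: float
    efs_y: float
    dx: float
    dy: float
    area_cm2: float
    truncated: bool = False


@dataclass
class EPDResult:
    """EPD as *additional depth* beyond the 1 cm reference plane.

    ``from_interface`` re-expresses it as depth below the bolus--phantom
    interface.  ``censored`` means the SAR never fell to 50% of the reference
    within the measured depth; ``value`` then holds the lower bound.
    """

    value: float
    censored: bool = False
    convention: str = "additional"
    column: tuple[float, ...] | None = None  # lateral position used

    @property
    def from_interface(self) -> float:
        return self.value + 1.0


@dataclass
class QAMetrics:
    """One scan's (or one session's) QA summary."""

    efs_x: float
    efs_y: float
    dx: float
    dy: float
    area_cm2: float
    epd_xz: EPDResult | None = None
    epd_yz: EPDResult | None = None
    isoline_components: dict[float, int] = field(default_factory=dict)


@dataclass
class DeltaEPDMap:
    """Per-column EPD and its relative deviation from the max-SAR EPD."""

    u: np.ndarray
    v: np.ndarray
    epd: np.ndarray  # cm, NaN where censored
    delta_pct: np.ndarray  # percent, NaN where censored
    epd_max_sar: float
    max_sar_uv: tuple[float, float]
    region: np.ndarray  # |DeltaEPD| <= threshold, censored columns excluded
    threshold_pct: float
    crosses_u0: bool  # region touches the u = 0 line (yz-plane)
    crosses_v0: bool  # region touches the v = 0 line (xz-plane)
    n_censored: int = 0


# ---------------------------------------------------------------------------
# Interpolation and resampling
# ---------------------------------------------------------------------------


def linear_interpolate(points: np.ndarray, values: np.ndarray, xi: np.ndarray):
    """Piecewise-linear (Delaunay) interpolation; NaN outside the hull."""
    return griddata(points, values, xi, method="linear")


def interpolate_plane(
    points: np.ndarray,
    values: np.ndarray,
    axis_names: tuple[str, str] = ("u", "v"),
    provenance: dict | None = None,
) -> RelativeSARGrid:
    """Interpolate scattered plane measurements onto the 0.1 cm analysis grid.

    Grid nodes sit at integer multiples of 0.1 cm so measurement points that
    share the origin anchoring coincide with nodes and are reproduced exactly.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or points.shape[0] < 3:
        raise ValueError("need >= 3 scattered (u, v) points")
    spread = points - points.mean(axis=0)
    if np.linalg.matrix_rank(spread, tol=1e-9) < 2:
        raise ValueError("point cloud is collinear; cannot triangulate")

    def axis(col):
        k0 = math.ceil(col.min() / GRID_SPACING - 1e-9)
        k1 = math.floor(col.max() / GRID_SPACING + 1e-9)
        return np.arange(k0, k1 + 1, dtype=float) * GRID_SPACING

    ua, va = axis(points[:, 0]), axis(points[:, 1])
    uu, vv = np.meshgrid(ua, va, indexing="ij")
    grid = linear_interpolate(points, values, (uu, vv))
    mask = np.isnan(grid)
    return RelativeSARGrid(
        u=ua,
        v=va,
        values=np.where(mask, 0.0, grid),
        mask=mask,
        axis_names=axis_names,
        provenance=provenance or {},
    )


def resample_plane(
    points: np.ndarray,
    values: np.ndarray,
    source_spacing: float,
    target_spacing: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Strict point subset mimicking a coarser scan resolution.

    No interpolation is performed: only those measured points whose (u, v)
    are integer multiples of the target spacing are kept, which requires the
    target to be an integer multiple of the source spacing and both grids to
    be anchored at the origin.
    """
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float)
    ratio = target_spacing / source_spacing
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"target spacing {target_spacing} is not an integer multiple of "
            f"source spacing {source_spacing}"
        )
    ratio = int(round(ratio))
    idx = np.round(points / source_spacing).astype(int)
    if not np.allclose(idx * source_spacing, points, atol=1e-6):
        raise ValueError("points are not anchored on the source-spacing grid")
    keep = np.all(idx % ratio == 0, axis=1)
    return points[keep], values[keep]


# ---------------------------------------------------------------------------
# Isolines and EFS
# ---------------------------------------------------------------------------


def extract_isolines(
    grid: RelativeSARGrid, levels: tuple[float, ...] = (50.0, 70.0, 80.0, 90.0, 98.0)
) -> IsolineSet:
    """Marching-squares contours at each level, plus region component counts.

    A level above the grid maximum yields an empty contour list, not an
    error.  Contour vertices are returned in grid coordinates (cm).
    """
    filled = np.where(grid.mask, -1.0, grid.values)
    contours: dict[float, list[np.ndarray]] = {}
    counts: dict[float, int] = {}
    for level in levels:
        polys = []
        for c in measure.find_contours(filled, level):
            xy = np.column_stack(
                [grid.u[0] + c[:, 0] * GRID_SPACING, grid.v[0] + c[:, 1] * GRID_SPACING]
            )
            polys.append(xy)
        contours[level] = polys
        region = (grid.values >= level) & grid.unmasked
        _, n = ndimage.label(region)
        counts[level] = int(n)
    return IsolineSet(levels=tuple(levels), contours=contours, component_counts=counts)


def compute_efs(grid: RelativeSARGrid, level: float = 50.0) -> EFSResult:
    """Field size and centre shift from the >= level region of an xy grid.

    Extents are taken from the marching-squares contour at ``level``
    (sub-cell linear accuracy), pooled over *all* connected components --
    split isolines under a thick bolus still produce a single bounding
    extent, as the published metric does.  The cell region supplies the area
    and the truncation check.  The centre is the midpoint of the extremes;
    the shifts are its offset from the visually aligned origin.
    """
    region = (grid.values >= level) & grid.unmasked
    if not region.any():
        raise ValueError(f"no cells at or above the {level}% level")
    iu, iv = np.nonzero(region)
    u_min, u_max = grid.u[iu.min()], grid.u[iu.max()]
    v_min, v_max = grid.v[iv.min()], grid.v[iv.max()]
    filled = np.where(grid.mask, -1.0, grid.values)
    polys = measure.find_contours(filled, level)
    if polys:
        pts = np.vstack(polys)
        cu = grid.u[0] + pts[:, 0] * GRID_SPACING
        cv = grid.v[0] + pts[:, 1] * GRID_SPACING
        # union with the cell extremes: at grid edges the contour cannot close
        u_min, u_max = min(u_min, cu.min()), max(u_max, cu.max())
        v_min, v_max = min(v_min, cv.min()), max(v_max, cv.max())
    truncated = (
        iu.min() == 0
        or iu.max() == grid.u.size - 1
        or iv.min() == 0
        or iv.max() == grid.v.size - 1
        or _touches_mask(region, grid.mask)
    )
    if truncated:
        warnings.warn(
            f"{level}% region touches the measured boundary; extents may be "
            "truncated (enlarge the scan bounding box)",
            TruncationWarning,
            stacklevel=2,
        )
    return EFSResult(
        efs_x=float(u_max - u_min),
        efs_y=float(v_max - v_min),
        dx=float((u_max + u_min) / 2.0),
        dy=float((v_max + v_min) / 2.0),
        area_cm2=float(region.sum()) * GRID_SPACING**2,
        truncated=truncated,
    )


def _touches_mask(region: np.ndarray, mask: np.ndarray) -> bool:
    """Does any region cell border a masked (outside-hull) cell?"""
    if not mask.any():
        return False
    grown = ndimage.binary_dilation(region)
    return bool((grown & mask).any())


# ---------------------------------------------------------------------------
# EPD
# ---------------------------------------------------------------------------


def _first_halving_depth(depths: np.ndarray, vals: np.ndarray) -> tuple[float, bool]:
    """Additional depth of the first downward crossing of 50% of vals[0].

    Linear interpolation between samples; returns ``(depth, censored)`` where
    a censored result carries the measured-range lower bound instead.
    """
    ref = vals[0]
    if ref <= 0:
        return float(depths[-1] - depths[0]), True
    target = 0.5 * ref
    below = vals < target
    for k in range(1, vals.size):
        if below[k] and not below[k - 1]:
            t = (vals[k - 1] - target) / (vals[k - 1] - vals[k])
            d = depths[k - 1] + t * (depths[k] - depths[k - 1])
            return float(d - depths[0]), False
    return float(depths[-1] - depths[0]), True


def compute_epd_from_plane(grid: RelativeSARGrid, depth_reference: float = 1.0) -> EPDResult:
    """EPD from an xz/yz plane grid: 50% of the 1 cm value at the plane's maximum.

    The lateral position of the plane's maximum SAR is located first (ties
    broken toward the smallest |lateral position|, then the smallest value);
    along that column the reference is the value at 1 cm depth and the EPD is
    the first 50% crossing, linearly interpolated.  A censored flag is set if
    no crossing occurs within the measured depth.
    """
    if grid.axis_names[1] != "depth":
        raise ValueError("plane grid must have ('u'|'v', 'depth') axes")
    depths = grid.v
    ref_rows = np.nonzero(np.abs(depths - depth_reference) < GRID_SPACING / 2)[0]
    if ref_rows.size == 0:
        raise ValueError(f"plane does not include the {depth_reference} cm depth row")
    if depths[-1] < depth_reference + 4.0 - 1e-9:
        raise ValueError("plane must extend >= 4 cm beyond the reference depth")
    vals = np.where(grid.mask, -np.inf, grid.values)
    vmax = vals.max()
    cand = np.nonzero(vals >= vmax - 1e-9)[0]  # row (lateral) indices of maxima
    lat = grid.u[cand]
    order = np.lexsort((lat, np.abs(lat)))
    i = int(cand[order[0]])
    col = grid.values[i, ref_rows[0] :]
    colmask = grid.mask[i, ref_rows[0] :]
    usable = np.nonzero(colmask)[0]
    end = usable[0] if usable.size else col.size
    value, censored = _first_halving_depth(
        depths[ref_rows[0] : ref_rows[0] + end], col[:end]
    )
    return EPDResult(value=value, censored=censored, column=(float(grid.u[i]),))


def compute_delta_epd(volume: SARVolume, threshold_pct: float = 5.0) -> DeltaEPDMap:
    """Per-column EPD map and its relative deviation from the max-SAR EPD.

    The max-SAR position is taken on the 1 cm layer (ties broken toward the
    smallest distance to the origin, then lexicographically).  Columns whose
    SAR never halves within the measured depth are censored: excluded from
    the threshold region and counted.  A censored max-SAR column aborts --
    the volume is too shallow to define the guideline EPD at all.
    """
    layer0 = volume.values[:, :, 0]
    vmax = layer0.max()
    iu, iv = np.nonzero(layer0 >= vmax - 1e-9)
    uu, vv = volume.u[iu], volume.v[iv]
    order = np.lexsort((vv, uu, uu**2 + vv**2))
    mi, mj = int(iu[order[0]]), int(iv[order[0]])

    nu, nv = volume.u.size, volume.v.size
    epd = np.full((nu, nv), np.nan)
    censored = np.zeros((nu, nv), dtype=bool)
    for i in range(nu):
        for j in range(nv):
            val, cens = _first_halving_depth(volume.depth, volume.values[i, j, :])
            censored[i, j] = cens
            if not cens:
                epd[i, j] = val
    if censored[mi, mj]:
        raise VolumeTooShallowError(
            "EPD at the max-SAR column is censored; extend the volume in depth"
        )
    epd_ref = float(epd[mi, mj])
    delta = (epd - epd_ref) / epd_ref * 100.0
    with np.errstate(invalid="ignore"):
        region = (np.abs(delta) <= threshold_pct) & ~censored

    du = float(np.min(np.diff(volume.u))) if nu > 1 else 1.0
    dv = float(np.min(np.diff(volume.v))) if nv > 1 else 1.0
    on_u0 = np.abs(volume.u) <= du / 2.0
    on_v0 = np.abs(volume.v) <= dv / 2.0
    return DeltaEPDMap(
        u=volume.u,
        v=volume.v,
        epd=epd,
        delta_pct=delta,
        epd_max_sar=epd_ref,
        max_sar_uv=(float(volume.u[mi]), float(volume.v[mj])),
        region=region,
        threshold_pct=threshold_pct,
        crosses_u0=bool(region[on_u0, :].any()),
        crosses_v0=bool(region[:, on_v0].any()),
        n_censored=int(censored.sum()),
    )


def epd_difference_at_threshold(epd_max_sar: float, threshold_pct: float = 5.0) -> float:
    """Absolute EPD difference (cm) at the DeltaEPD threshold boundary.

    Inverts the DeltaEPD definition: |EPD(x,y) - EPD(maxSAR)| at
    DeltaEPD = threshold is ``threshold/100 * EPD(maxSAR)``.
    """
    if epd_max_sar <= 0:
        raise ValueError("EPD(maxSAR) must be positive")
    return threshold_pct / 100.0 * epd_max_sar


def volume_from_scan(
    points_uvd: np.ndarray, values_pct: np.ndarray
) -> SARVolume:
    """Assemble a volume-scan point list into a dense (u, v, depth) array."""
    pts = np.asarray(points_uvd, dtype=float)
    vals = np.asarray(values_pct, dtype=float)
    ua = np.unique(pts[:, 0])
    va = np.unique(pts[:, 1])
    da = np.unique(pts[:, 2])
    cube = np.full((ua.size, va.size, da.size), np.nan)
    i = np.searchsorted(ua, pts[:, 0])
    j = np.searchsorted(va, pts[:, 1])
    k = np.searchsorted(da, pts[:, 2])
    cube[i, j, k] = vals
    if np.isnan(cube).any():
        raise ValueError("volume scan is not a complete rectangular grid")
    return SARVolume(u=ua, v=va, depth=da, values=cube)
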