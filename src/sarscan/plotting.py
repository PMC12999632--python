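"""Plane plots: interpolated relative-SAR colour mesh with isolines.

Mirrors the standard presentation of measured SAR planes: the 0.1 cm
interpolated grid as a colour mesh, measurement positions as dots, and the
50/70/80/90/98% isolines overlaid.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .metrics import RelativeSARGrid, extract_isolines

__all__ = ["plot_plane"]


def plot_plane(
    grid: RelativeSARGrid,
    out_path,
    measurement_points: np.ndarray | None = None,
    levels: tuple[float, ...] = (50.0, 70.0, 80.0, 90.0, 98.0),
    title: str | None = None,
) -> None:
    """Write a PNG of the plane with isolines (and optional scan positions)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    vals = np.where(grid.mask, np.nan, grid.values)
    mesh = ax.pcolormesh(grid.u, grid.v, vals.T, shading="nearest", cmap="jet",
                         vmin=0, vmax=max(100.0, float(np.nanmax(vals))))
    iso = extract_isolines(grid, levels=levels)
    for level in levels:
        for poly in iso.contours[level]:
            ax.plot(poly[:, 0], poly[:, 1], "k-", lw=0.7)
    if measurement_points is not None and len(measurement_points):
        ax.plot(measurement_points[:, 0], measurement_points[:, 1], "k.", ms=2)
    ax.set_xlabel(f"{grid.axis_names[0]} [cm]")
    ax.set_ylabel(f"{grid.axis_names[1]} [cm]")
    if grid.axis_names[1] == "depth":
        ax.invert_yaxis()
    ax.set_aspect("equal")
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax, label="relative SAR [%]")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
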