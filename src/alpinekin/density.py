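"""Angle x velocity occurrence grids and their rendering.

Bivariate histograms show at which angular position a given angular velocity
mainly occurs; grids are normalized linearly to their own maximum within each
(leg, discipline) panel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

DEFAULT_ANGLE_EDGES = np.arange(30.0, 180.0 + 1e-9, 2.5)  # deg
DEFAULT_VELOCITY_EDGES = np.arange(-200.0, 200.0 + 1e-9, 5.0)  # deg/s

_PANEL_ORDER = ("SL", "GS", "SG", "DH")


@dataclass
class DensityGrid:
    """2D occurrence histogram over fixed angle and velocity edges."""

    angle_edges: np.ndarray
    velocity_edges: np.ndarray
    counts: np.ndarray  # shape (n_angle_bins, n_velocity_bins)
    leg: Optional[str] = None
    discipline: Optional[str] = None
    n_clipped: int = 0
    normalized: bool = False


def density_grid(
    angles: Sequence[float],
    velocities: Sequence[float],
    angle_edges: Optional[np.ndarray] = None,
    velocity_edges: Optional[np.ndarray] = None,
    leg: Optional[str] = None,
    discipline: Optional[str] = None,
) -> DensityGrid:
    """Histogram (angle, velocity) sample pairs onto a fixed grid.

    Out-of-range samples are clipped into the edge bins and reported via
    ``n_clipped`` — every input sample is counted exactly once.
    """
    angles = np.asarray(angles, dtype=float)
    velocities = np.asarray(velocities, dtype=float)
    if angles.size == 0 or angles.shape != velocities.shape:
        raise ValueError("need matched, non-empty angle and velocity samples")
    ae = DEFAULT_ANGLE_EDGES if angle_edges is None else np.asarray(angle_edges, float)
    ve = DEFAULT_VELOCITY_EDGES if velocity_edges is None else np.asarray(velocity_edges, float)
    if np.any(np.diff(ae) <= 0) or np.any(np.diff(ve) <= 0):
        raise ValueError("bin edges must be strictly ascending")

    out_of_range = (
        (angles < ae[0]) | (angles > ae[-1]) | (velocities < ve[0]) | (velocities > ve[-1])
    )
    # nudge strictly inside so np.histogram2d assigns clipped samples to edge bins
    a = np.clip(angles, ae[0], np.nextafter(ae[-1], -np.inf))
    v = np.clip(velocities, ve[0], np.nextafter(ve[-1], -np.inf))
    counts, _, _ = np.histogram2d(a, v, bins=[ae, ve])
    return DensityGrid(
        angle_edges=ae,
        velocity_edges=ve,
        counts=counts,
        leg=leg,
        discipline=discipline,
        n_clipped=int(out_of_range.sum()),
    )


def normalize_grid(grid: DensityGrid) -> DensityGrid:
    """Linear scaling by the grid's own maximum; all-zero grids pass through."""
    peak = grid.counts.max()
    counts = grid.counts / peak if peak > 0 else grid.counts.copy()
    return replace(grid, counts=counts, normalized=True)


def grid_to_csv(grid: DensityGrid, path) -> None:
    """Export a grid as CSV with velocity-edge header and angle-edge index."""
    import pandas as pd

    va = 0.5 * (grid.velocity_edges[:-1] + grid.velocity_edges[1:])
    aa = 0.5 * (grid.angle_edges[:-1] + grid.angle_edges[1:])
    pd.DataFrame(grid.counts, index=aa, columns=va).to_csv(path, index_label="angle_deg")


def render(grids: Dict[Tuple[str, str], DensityGrid], path) -> None:
    """Panel matrix (disciplines x IL/OL) of normalized grids, blue-to-red.

    ``grids`` maps (discipline, leg) to a DensityGrid; missing cells are
    left blank.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not grids:
        raise ValueError("no grids to render")
    disciplines = [d for d in _PANEL_ORDER if any(k[0] == d for k in grids)]
    disciplines += sorted({k[0] for k in grids} - set(disciplines))
    legs = ("IL", "OL")
    fig, axes = plt.subplots(
        len(disciplines), len(legs),
        figsize=(3.2 * len(legs), 2.6 * len(disciplines)),
        squeeze=False, sharex=True, sharey=True,
    )
    for i, disc in enumerate(disciplines):
        for j, leg in enumerate(legs):
            ax = axes[i][j]
            grid = grids.get((disc, leg))
            if grid is None:
                ax.axis("off")
                continue
            g = grid if grid.normalized else normalize_grid(grid)
            ax.imshow(
                g.counts,
                origin="lower",
                aspect="auto",
                cmap="jet",
                vmin=0.0,
                vmax=1.0,
                extent=(
                    g.velocity_edges[0], g.velocity_edges[-1],
                    g.angle_edges[0], g.angle_edges[-1],
                ),
            )
            ax.set_title(f"{disc} {leg}", fontsize=9)
            if i == len(disciplines) - 1:
                ax.set_xlabel("angular velocity (deg/s)")
            if j == 0:
                ax.set_ylabel("angle (deg)")
    fig.tight_layout()
    fig.savefig(path, dpi=110, metadata={"Software": None})
    plt.close(fig)


def occupied_velocity_extent(grid: DensityGrid, level: float = 0.05) -> float:
    """Width (deg/s) of the velocity band whose normalized occupancy > level."""
    g = grid if grid.normalized else normalize_grid(grid)
    cols = np.any(g.counts > level, axis=0)
    if not cols.any():
        return 0.0
    idx = np.where(cols)[0]
    return float(g.velocity_edges[idx[-1] + 1] - g.velocity_edges[idx[0]])
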