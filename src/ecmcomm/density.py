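"""Z-scored local fiber density in quantification windows over simulation time.

A quantification window is a square with an edge of one cell diameter, placed
relative to the current cell boundary and facing either the communication
partner or a fixed orientation (single cells).  Fiber "volume" inside a window
is the clipped fiber length rescaled to the fiber's rest length at onset,
which conserves total fiber material under the 2D representation of buckling.
Densities are normalized to z-scores against background windows tiled over the
domain at simulation onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mechanics import SimulationTrajectory

__all__ = [
    "QuantificationWindow",
    "BackgroundStats",
    "DensityTimeSeries",
    "fiber_volume_in_window",
    "compute_background_stats",
    "extract_density_timeseries",
    "extract_single_cell_series",
    "window_for_cell",
]


@dataclass
class QuantificationWindow:
    center: np.ndarray  # (2,) AU
    edge: float  # AU, one cell diameter

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        cx, cy = self.center
        h = self.edge / 2.0
        return cx - h, cx + h, cy - h, cy + h


@dataclass
class BackgroundStats:
    mean: float
    std: float
    n_windows: int
    tiling_step: float  # AU

    def zscore(self, volume):
        return (np.asarray(volume, dtype=float) - self.mean) / self.std


@dataclass
class DensityTimeSeries:
    """Per-frame z-scored density with a validity mask."""

    z: np.ndarray
    valid: np.ndarray
    frame_interval: float = 1.0
    cell_id: str = ""
    pair_id: str = ""
    run_id: str = ""
    window_distance: float = 0.0  # cell diameters
    offset_perp: float = 0.0  # cell diameters

    def __len__(self) -> int:
        return int(self.z.shape[0])


def _clip_lengths(p0: np.ndarray, p1: np.ndarray, bounds) -> np.ndarray:
    """Liang-Barsky clipping of segments to an axis-aligned box; returns inner lengths."""
    xmin, xmax, ymin, ymax = bounds
    d = p1 - p0
    t0 = np.zeros(p0.shape[0])
    t1 = np.ones(p0.shape[0])
    for axis, (lo, hi) in enumerate(((xmin, xmax), (ymin, ymax))):
        p = d[:, axis]
        q0 = p0[:, axis]
        with np.errstate(divide="ignore", invalid="ignore"):
            tlo = np.where(p != 0.0, (lo - q0) / p, -np.inf)
            thi = np.where(p != 0.0, (hi - q0) / p, np.inf)
        tmin = np.minimum(tlo, thi)
        tmax = np.maximum(tlo, thi)
        inside = (q0 >= lo) & (q0 <= hi)
        tmin = np.where(p == 0.0, np.where(inside, -np.inf, np.inf), tmin)
        tmax = np.where(p == 0.0, np.where(inside, np.inf, -np.inf), tmax)
        t0 = np.maximum(t0, tmin)
        t1 = np.minimum(t1, tmax)
    frac = np.clip(t1 - t0, 0.0, 1.0)
    frac[t1 < t0] = 0.0
    return frac * np.linalg.norm(d, axis=1)


def fiber_volume_in_window(
    traj: SimulationTrajectory, step: int, window: QuantificationWindow
) -> float:
    """Accumulated fiber volume in a window at a simulation step.

    Each fiber contributes its in-window length rescaled by its onset-to-current
    length ratio, so a fiber fully inside the window contributes its onset
    length regardless of deformation.
    """
    pos = traj.positions[step]
    fib = traj.geometry.fibers
    p0, p1 = pos[fib[:, 0]], pos[fib[:, 1]]
    inner = _clip_lengths(p0, p1, window.bounds)
    length = np.linalg.norm(p1 - p0, axis=1)
    l0 = traj.geometry.rest_lengths
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(length > 0, inner * l0 / length, 0.0)
    return float(contrib.sum())


def compute_background_stats(
    traj: SimulationTrajectory,
    tiling_step_diameters: float = 0.02,
    exclusion_margin_diameters: float = 1.0,
) -> BackgroundStats:
    """Background mean/std of window densities tiled over the onset frame.

    The domain is tiled with windows of one cell-diameter edge at steps of
    ``tiling_step_diameters`` cell diameters per axis; windows intersecting the
    window centered on any cell are excluded.  Implemented by rasterizing the
    onset fiber length onto a grid of the tiling step and box-summing with an
    integral image, which makes the dense tiling tractable.
    """
    geom = traj.geometry
    d = geom.cell_diameter
    h = geom.domain_halfwidth
    step = tiling_step_diameters * d
    n_bins = int(np.floor(2.0 * h / step))
    w_bins = max(int(round(d / step)), 1)
    if n_bins <= w_bins:
        raise ValueError("tiling step too coarse for the domain")

    # rasterize onset fiber length (sampled along each fiber) onto the grid
    pos = traj.positions[0]
    p0 = pos[geom.fibers[:, 0]]
    p1 = pos[geom.fibers[:, 1]]
    l0 = geom.rest_lengths
    m = max(int(np.ceil(2.0 * l0.mean() / step)), 3)
    t = (np.arange(m) + 0.5) / m
    pts = p0[:, None, :] + t[None, :, None] * (p1 - p0)[:, None, :]
    wts = np.repeat(l0 / m, m)
    pts = pts.reshape(-1, 2)
    grid, _, _ = np.histogram2d(
        pts[:, 0],
        pts[:, 1],
        bins=n_bins,
        range=[[-h, -h + n_bins * step], [-h, -h + n_bins * step]],
        weights=wts,
    )
    integral = np.zeros((n_bins + 1, n_bins + 1))
    integral[1:, 1:] = np.cumsum(np.cumsum(grid, axis=0), axis=1)
    sums = (
        integral[w_bins:, w_bins:]
        - integral[:-w_bins, w_bins:]
        - integral[w_bins:, :-w_bins]
        + integral[:-w_bins, :-w_bins]
    )  # (n_bins - w_bins + 1)^2 window sums; window [i, i + w_bins) bins

    # exclude windows intersecting the cell-centered windows
    n_pos = sums.shape[0]
    starts = -h + np.arange(n_pos) * step  # window lower edge per axis
    centers = starts + w_bins * step / 2.0
    mask = np.ones((n_pos, n_pos), dtype=bool)
    # windows of edge d intersect the cell-centered window (edge excl) iff the
    # center separation is below half the two edges, per axis
    excl = exclusion_margin_diameters * d
    for v in geom.cell_voids:
        near_x = np.abs(centers - v.center[0]) < (d / 2.0 + excl / 2.0)
        near_y = np.abs(centers - v.center[1]) < (d / 2.0 + excl / 2.0)
        mask &= ~(near_x[:, None] & near_y[None, :])
    vals = sums[mask]
    mean = float(vals.mean())
    std = float(vals.std(ddof=1))
    if not np.isfinite(std) or std <= 1e-9 * max(abs(mean), 1.0):
        raise ValueError("degenerate network: zero background density variance")
    return BackgroundStats(mean=mean, std=std, n_windows=int(vals.size), tiling_step=step)


def window_for_cell(
    traj: SimulationTrajectory,
    step: int,
    cell: int,
    direction: np.ndarray,
    window_distance: float = 0.0,
    offset_perp: float = 0.0,
    anchor: str = "trend",
) -> QuantificationWindow:
    """Window anchored to the cell boundary along a direction.

    The inner edge of the window is tangent to the cell boundary at the point
    nearest the partner; ``window_distance`` (cell diameters) shifts it further
    along the connecting direction, ``offset_perp`` perpendicular to it.  The
    boundary radius is taken from the linearized contraction trend by default
    (``anchor="trend"``): the window follows the contracting boundary without
    inheriting the cell's own step-to-step contraction noise through its
    placement.  ``anchor="current"`` uses the exact instantaneous radius and
    ``anchor="onset"`` the step-0 radius.
    """
    geom = traj.geometry
    d = geom.cell_diameter
    u = np.asarray(direction, dtype=float)
    u = u / np.linalg.norm(u)
    perp = np.array([-u[1], u[0]])
    if anchor == "trend":
        r = traj.cell_radius_trend(step, cell)
    elif anchor == "current":
        r = traj.cell_radius(step, cell)
    elif anchor == "onset":
        r = traj.cell_radius(0, cell)
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    center = (
        geom.cell_voids[cell].center
        + (r + window_distance * d + d / 2.0) * u
        + offset_perp * d * perp
    )
    return QuantificationWindow(center=center, edge=d)


def _window_in_domain(window: QuantificationWindow, halfwidth: float) -> bool:
    xmin, xmax, ymin, ymax = window.bounds
    return (
        xmin >= -halfwidth and xmax <= halfwidth and ymin >= -halfwidth and ymax <= halfwidth
    )


def extract_density_timeseries(
    traj: SimulationTrajectory,
    background: BackgroundStats,
    cell: int,
    partner: int | None = None,
    direction: np.ndarray | None = None,
    window_distance: float = 0.0,
    offset_perp: float = 0.0,
    run_id: str = "",
    anchor: str = "trend",
) -> DensityTimeSeries:
    """Z-scored density time series for one cell's quantification window.

    The window is re-anchored at every step to the contracting cell boundary
    (see :func:`window_for_cell` for the anchor conventions), facing
    ``partner`` (or a fixed ``direction`` for single cells), and z-scored
    against the onset background.  Frames whose window leaves the domain are
    flagged invalid.
    """
    geom = traj.geometry
    if direction is None:
        if partner is None:
            raise ValueError("either partner or direction must be given")
        direction = geom.cell_voids[partner].center - geom.cell_voids[cell].center
    n = traj.n_steps + 1
    z = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for t in range(n):
        win = window_for_cell(
            traj, t, cell, direction, window_distance, offset_perp, anchor=anchor
        )
        if not _window_in_domain(win, geom.domain_halfwidth):
            continue
        vol = fiber_volume_in_window(traj, t, win)
        z[t] = background.zscore(vol)
        valid[t] = True
    pair_id = f"{run_id}:{cell}-{partner}" if partner is not None else ""
    return DensityTimeSeries(
        z=z,
        valid=valid,
        cell_id=f"{run_id}:{cell}",
        pair_id=pair_id,
        run_id=run_id,
        window_distance=window_distance,
        offset_perp=offset_perp,
    )


def extract_single_cell_series(
    traj: SimulationTrajectory,
    background: BackgroundStats,
    cell: int = 0,
    window_distance: float = 0.0,
    run_id: str = "",
) -> DensityTimeSeries:
    """Mean of four windows (up/down/left/right) around a single cell."""
    dirs = [np.array(v, dtype=float) for v in ((1, 0), (-1, 0), (0, 1), (0, -1))]
    series = [
        extract_density_timeseries(
            traj,
            background,
            cell,
            direction=u,
            window_distance=window_distance,
            run_id=run_id,
        )
        for u in dirs
    ]
    zs = np.stack([s.z for s in series])
    valid = np.all(np.stack([s.valid for s in series]), axis=0)
    z = np.where(valid, np.nanmean(zs, axis=0), np.nan)
    return DensityTimeSeries(
        z=z,
        valid=valid,
        cell_id=f"{run_id}:{cell}",
        run_id=run_id,
        window_distance=window_distance,
    )
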