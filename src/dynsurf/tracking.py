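"""Trajectory linking, cumulative migration distance, and mean velocity.

The velocity statistic mirrors the time-lapse analysis of the migration
assays: positions are resampled to an hourly grid, per-hour displacements
are summed into a cumulative path length, and the mean migration velocity
is the ordinary-least-squares slope of that cumulative curve against time.
Per-condition summaries report mean +/- SEM over cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Trajectory",
    "VelocityEstimate",
    "link_tracks",
    "cumulative_distance",
    "mean_velocity",
    "condition_velocity",
    "velocity_density_profile",
]


@dataclass
class Trajectory:
    """One cell's time-ordered positions at nominally uniform spacing."""

    cell_id: str
    t: np.ndarray  # hr
    x: np.ndarray  # um
    y: np.ndarray  # um
    condition: str | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def net_displacement(self) -> float:
        if len(self) < 2:
            return 0.0
        return float(np.hypot(self.x[-1] - self.x[0], self.y[-1] - self.y[0]))


@dataclass
class VelocityEstimate:
    """OLS fit of cumulative path length on time for one cell."""

    cell_id: str
    velocity: float  # um/hr, slope
    intercept: float  # um
    r_squared: float
    cumulative: pd.DataFrame  # columns t_hr, cum_um
    condition: str | None = None


def link_tracks(frames, max_step: float, condition: str | None = None) -> list[Trajectory]:
    """Greedy nearest-neighbor linking of per-frame detections into tracks.

    Parameters
    ----------
    frames
        Time-ordered sequence of ``(t_hr, positions)`` pairs where
        ``positions`` is an ``(n, 2)`` array of (x, y) in um.
    max_step
        Links longer than this (um) are refused; the detection starts a
        new track.

    Candidate links within each frame transition are taken in order of
    increasing distance, ties broken by (track index, detection index), so
    the output is deterministic.  Crossing cells closer than ``max_step``
    may swap identity; that is the documented greedy behavior.
    """
    if max_step <= 0:
        raise ValueError("max_step must be > 0")
    tracks: list[dict] = []  # each: {"t": [...], "xy": [...], "open": bool}
    active: list[int] = []
    last_t = -np.inf
    for t, pts in frames:
        if t <= last_t:
            raise ValueError("frames must be strictly time-ordered")
        last_t = t
        pts = np.atleast_2d(np.asarray(pts, dtype=float)).reshape(-1, 2)
        n_det = len(pts)
        if not active:
            new_active = []
            for j in range(n_det):
                tracks.append({"t": [t], "xy": [pts[j]]})
                new_active.append(len(tracks) - 1)
            active = new_active
            continue
        ends = np.array([tracks[i]["xy"][-1] for i in active])
        if n_det:
            dist = np.linalg.norm(ends[:, None, :] - pts[None, :, :], axis=2)
            pairs = [
                (dist[a, j], a, j)
                for a in range(len(active))
                for j in range(n_det)
                if dist[a, j] <= max_step
            ]
        else:
            pairs = []
        pairs.sort(key=lambda p: (p[0], p[1], p[2]))
        used_tracks: set[int] = set()
        used_dets: set[int] = set()
        assignment: dict[int, int] = {}
        for d, a, j in pairs:
            if a in used_tracks or j in used_dets:
                continue
            used_tracks.add(a)
            used_dets.add(j)
            assignment[j] = active[a]
        new_active = []
        for j in range(n_det):
            if j in assignment:
                idx = assignment[j]
                tracks[idx]["t"].append(t)
                tracks[idx]["xy"].append(pts[j])
            else:
                tracks.append({"t": [t], "xy": [pts[j]]})
                idx = len(tracks) - 1
            new_active.append(idx)
        active = new_active
    out = []
    for i, tr in enumerate(tracks):
        xy = np.array(tr["xy"])
        out.append(
            Trajectory(
                cell_id=f"track_{i:03d}",
                t=np.array(tr["t"]),
                x=xy[:, 0],
                y=xy[:, 1],
                condition=condition,
            )
        )
    return out


def cumulative_distance(traj: Trajectory, resample: float = 1.0) -> pd.DataFrame:
    """Cumulative path length on a regular time grid.

    Positions are resampled to the grid ``t0, t0+resample, ...`` by taking
    the *nearest* recorded sample (no interpolation, so measured path
    lengths are preserved); Euclidean displacements between consecutive
    grid positions are then summed.  Returns a frame with columns
    ``t_hr`` and ``cum_um``.
    """
    if len(traj) < 2:
        raise ValueError("trajectory needs >= 2 samples")
    native = float(np.median(np.diff(traj.t)))
    if resample < native - 1e-9:
        raise ValueError(
            f"resample interval {resample} hr is finer than the native sampling ({native} hr)"
        )
    span = traj.t[-1] - traj.t[0]
    if span < resample:
        raise ValueError("trajectory shorter than one resample interval")
    grid = traj.t[0] + resample * np.arange(int(np.floor(span / resample + 1e-9)) + 1)
    idx = np.abs(traj.t[None, :] - grid[:, None]).argmin(axis=1)
    gx, gy = traj.x[idx], traj.y[idx]
    steps = np.hypot(np.diff(gx), np.diff(gy))
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    return pd.DataFrame({"t_hr": grid, "cum_um": cum})


def mean_velocity(series: pd.DataFrame, cell_id: str = "", condition: str | None = None) -> VelocityEstimate:
    """Mean migration velocity: OLS slope of cumulative distance vs time."""
    t = np.asarray(series["t_hr"], dtype=float)
    c = np.asarray(series["cum_um"], dtype=float)
    if len(t) < 3:
        raise ValueError("need >= 3 cumulative points for a slope")
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis (all t equal)")
    fit = stats.linregress(t, c)
    r2 = float(fit.rvalue**2) if np.std(c) > 0 else 1.0
    return VelocityEstimate(
        cell_id=cell_id,
        velocity=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        cumulative=series,
        condition=condition,
    )


def condition_velocity(trajectories, resample: float = 1.0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell velocity estimates plus a per-condition summary.

    Returns ``(cells, summary)``: per-cell rows (cell_id, condition,
    velocity, intercept, r_squared) and per-condition mean/SEM/n over
    cells.  Trajectories too short to resample are skipped.
    """
    rows = []
    for traj in trajectories:
        if len(traj) < 3:
            continue
        est = mean_velocity(
            cumulative_distance(traj, resample), cell_id=traj.cell_id, condition=traj.condition
        )
        rows.append(
            {
                "cell_id": est.cell_id,
                "condition": est.condition,
                "velocity_um_hr": est.velocity,
                "intercept_um": est.intercept,
                "r_squared": est.r_squared,
            }
        )
    cells = pd.DataFrame(rows, columns=["cell_id", "condition", "velocity_um_hr", "intercept_um", "r_squared"])
    if cells.empty:
        summary = pd.DataFrame(columns=["condition", "mean_velocity_um_hr", "sem_um_hr", "n_cells"])
        return cells, summary
    grouped = cells.groupby("condition", dropna=False)["velocity_um_hr"]
    summary = pd.DataFrame(
        {
            "mean_velocity_um_hr": grouped.mean(),
            "sem_um_hr": grouped.sem(),
            "n_cells": grouped.size(),
        }
    ).reset_index()
    return cells, summary


def velocity_density_profile(estimates: pd.DataFrame) -> pd.DataFrame:
    """Summarize velocity by ligand (affinity, density) group.

    ``estimates`` needs columns ``affinity``, ``density``, and
    ``velocity_um_hr`` (one row per cell).  Returns mean, SEM and n per
    group, sorted by affinity then density.
    """
    cols = ["affinity", "density", "mean_velocity_um_hr", "sem_um_hr", "n_cells"]
    if estimates.empty:
        return pd.DataFrame(columns=cols)
    grouped = estimates.groupby(["affinity", "density"])["velocity_um_hr"]
    out = pd.DataFrame(
        {
            "mean_velocity_um_hr": grouped.mean(),
            "sem_um_hr": grouped.sem(),
            "n_cells": grouped.size(),
        }
    ).reset_index()
    return out.sort_values(["affinity", "density"], kind="mergesort").reset_index(drop=True)
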