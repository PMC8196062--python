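"""Trajectory kinematics for a single chamber deployment.

A deployment's digitized larva positions (cm, arena-centered, camera frame)
are reduced to a 1 Hz series from which instantaneous speeds, turning angles
and position bearings are computed. Position bearings — the angular location
of the larva within the arena, not its heading — are the quantities the
orientation tests operate on.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circstats import AngleSample

log = logging.getLogger(__name__)

__all__ = [
    "Trajectory",
    "KinematicsSummary",
    "subsample_1hz",
    "instantaneous_speeds",
    "turning_angles",
    "position_bearings",
    "summarize_kinematics",
    "read_trajectories_csv",
    "write_trajectories_csv",
    "pixels_to_cm",
]

#: tolerated overshoot (cm) of a position beyond the arena wall
WALL_TOLERANCE_CM = 0.5
#: bearings are ill-conditioned this close (cm) to the arena center
CENTER_CUTOFF_CM = 0.5


@dataclass
class Trajectory:
    """One larva's positions in arena coordinates.

    t is seconds from acquisition start (strictly increasing); x, y are cm
    from the arena center with y along the camera-frame "up" axis. The
    acclimation interval at the start of a deployment is kept in the data and
    removed by :func:`subsample_1hz`.
    """

    deployment_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_radius_cm: float = 10.0
    acclimation_s: float = 300.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape):
            raise ValueError(f"{self.deployment_id}: t/x/y length mismatch")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError(f"{self.deployment_id}: timestamps not strictly increasing")
        rmax = float(np.max(np.hypot(self.x, self.y), initial=0.0))
        if rmax > self.arena_radius_cm + WALL_TOLERANCE_CM:
            raise ValueError(
                f"{self.deployment_id}: position {rmax:.2f} cm from center exceeds "
                f"arena radius {self.arena_radius_cm} cm"
            )

    def __len__(self) -> int:
        return self.t.size


@dataclass
class KinematicsSummary:
    mean_speed_cm_s: float
    mean_turning_deg: float
    n_points: int


def subsample_1hz(raw: Trajectory) -> Trajectory:
    """Reduce an arbitrary-rate track to one point per whole second.

    The acclimation window is dropped, then for every integer-second tick the
    nearest frame at or before the tick is kept. Already-1 Hz input (after
    trimming) passes through unchanged.
    """
    if len(raw) < 2:
        raise ValueError(f"{raw.deployment_id}: need at least 2 points")
    keep = raw.t >= raw.acclimation_s
    t, x, y = raw.t[keep], raw.x[keep], raw.y[keep]
    if t.size < 2 or t[-1] - t[0] < 1.0:
        raise ValueError(
            f"{raw.deployment_id}: < 2 s of data after removing the "
            f"{raw.acclimation_s:.0f} s acclimation window"
        )
    ticks = np.arange(math.ceil(t[0]), math.floor(t[-1]) + 1.0)
    # last frame at or before each tick
    idx = np.searchsorted(t, ticks, side="right") - 1
    idx = np.unique(idx[idx >= 0])
    if idx.size < 2:
        raise ValueError(f"{raw.deployment_id}: < 2 s of 1 Hz coverage")
    return Trajectory(
        deployment_id=raw.deployment_id,
        t=t[idx],
        x=x[idx],
        y=y[idx],
        arena_radius_cm=raw.arena_radius_cm,
        acclimation_s=0.0,
    )


def instantaneous_speeds(traj: Trajectory) -> np.ndarray:
    """Speed between consecutive points, cm/s; length n-1."""
    if len(traj) < 2:
        raise ValueError(f"{traj.deployment_id}: need at least 2 points for speeds")
    dt = np.diff(traj.t)
    return np.hypot(np.diff(traj.x), np.diff(traj.y)) / dt


def turning_angles(traj: Trajectory) -> np.ndarray:
    """Absolute turning angle at each interior point, degrees in [0, 180].

    The angle between successive displacement vectors: 0° is a straight
    continuation, 180° a full reversal. Steps with zero displacement carry no
    direction and are skipped (logged); if nothing remains the series is
    empty and a warning is logged.
    """
    if len(traj) < 3:
        raise ValueError(f"{traj.deployment_id}: need at least 3 points for turning angles")
    dx, dy = np.diff(traj.x), np.diff(traj.y)
    norm = np.hypot(dx, dy)
    moving = norm > 0
    n_zero = int(np.sum(~moving))
    if n_zero:
        log.info("%s: skipped %d zero-length steps in turning angles", traj.deployment_id, n_zero)
    dx, dy = dx[moving], dy[moving]
    if dx.size < 2:
        log.warning("%s: no consecutive moving steps; empty turning series", traj.deployment_id)
        return np.empty(0)
    # exterior angle between step i and step i+1 via the cross/dot construction
    cross = dx[:-1] * dy[1:] - dy[:-1] * dx[1:]
    dot = dx[:-1] * dx[1:] + dy[:-1] * dy[1:]
    return np.abs(np.degrees(np.arctan2(cross, dot)))


def position_bearings(
    traj: Trajectory, center_cutoff_cm: float = CENTER_CUTOFF_CM
) -> tuple[AngleSample, np.ndarray]:
    """Bearing of each position from the arena center, camera frame.

    Degrees clockwise from the camera-frame "up" axis: (0, +d) maps to 0°,
    (+d, 0) to 90°. Points closer than ``center_cutoff_cm`` to the center are
    excluded (bearing ill-conditioned there) and logged. Returns the sample
    together with the timestamps of the retained points so the chamber
    heading can be looked up per bearing.
    """
    rad = np.hypot(traj.x, traj.y)
    keep = rad >= center_cutoff_cm
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        log.info(
            "%s: dropped %d positions within %.2f cm of arena center",
            traj.deployment_id, n_dropped, center_cutoff_cm,
        )
    if not np.any(keep):
        raise ValueError(f"{traj.deployment_id}: all positions at arena center")
    bearings = np.degrees(np.arctan2(traj.x[keep], traj.y[keep])) % 360.0
    return AngleSample(bearings, label=f"{traj.deployment_id} camera"), traj.t[keep]


def summarize_kinematics(traj: Trajectory) -> KinematicsSummary:
    """Per-deployment mean speed and mean absolute turning angle."""
    speeds = instantaneous_speeds(traj)
    turns = turning_angles(traj)
    return KinematicsSummary(
        mean_speed_cm_s=float(np.mean(speeds)),
        mean_turning_deg=float(np.mean(turns)) if turns.size else float("nan"),
        n_points=len(traj),
    )


def pixels_to_cm(x_px, y_px, extent_px: float, diameter_cm: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Convert raw pixel coordinates using the detected arena extent.

    ``extent_px`` is the arena diameter in pixels as detected in the video;
    the known physical diameter fixes the scale.
    """
    if extent_px <= 0:
        raise ValueError("arena extent in pixels must be positive")
    scale = diameter_cm / extent_px
    return np.asarray(x_px, float) * scale, np.asarray(y_px, float) * scale


def read_trajectories_csv(path) -> dict[str, Trajectory]:
    """Read a multi-deployment trajectory table.

    Columns: deployment_id, t_s, x_cm, y_cm (header required).
    """
    df = pd.read_csv(path)
    required = {"deployment_id", "t_s", "x_cm", "y_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trajectory columns {sorted(missing)}")
    out = {}
    for dep, g in df.groupby("deployment_id", sort=True):
        g = g.sort_values("t_s")
        out[str(dep)] = Trajectory(
            deployment_id=str(dep),
            t=g["t_s"].to_numpy(),
            x=g["x_cm"].to_numpy(),
            y=g["y_cm"].to_numpy(),
        )
    return out


def write_trajectories_csv(trajectories, path) -> None:
    frames = [
        pd.DataFrame(
            {"deployment_id": tr.deployment_id, "t_s": tr.t, "x_cm": tr.x, "y_cm": tr.y}
        )
        for tr in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
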