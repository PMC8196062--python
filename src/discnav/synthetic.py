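"""Seeded generator of synthetic chamber deployments with known ground truth.

Each larva performs a biased correlated random walk inside the 10 cm-radius
arena: at every 1 s step its heading is drawn from a von Mises distribution
centered on a circular blend of the previous heading (directional
persistence) and the goal direction (attraction, concentration
``kappa_goal``), plus a wrapped-normal turning jitter whose standard
deviation declines linearly with age — older larvae swim straighter. Step
length is the age-dependent mean speed with truncated-normal noise; the wall
reflects. The chamber itself rotates (constant rate or a noisy drift), so
the recorded camera-frame positions are the world-frame walk counter-rotated
by the chamber heading, exactly the confound the frame-correction stage must
undo.

The orientation-strategy hypotheses are generative modes:

* H0_none — no goal, uniform per-step headings;
* H1_single_bearing — every larva shares one constant compass goal;
* H2_condition_dependent — the goal flips 180° at a switch age
  (east early, west late by default);
* H3_context_dependent — the goal is the bearing to the nearest point of a
  configured reef line from the deployment position;
* H4_mixed — each larva draws its goal from a discrete mixture.

Independently of strategy, a configurable fraction of larvae carry their
goal in the *arena* frame (they track a chamber feature); these are the
ground-truth device-biased individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import CompassSeries, write_compass_csv
from .kinematics import Trajectory, write_trajectories_csv
from .references import DeploymentContext, initial_bearing

__all__ = ["SimConfig", "Truth", "SimulatedDeployment", "simulate_trajectory",
           "simulate_cohort", "write_cohort"]

STRATEGIES = ("H0_none", "H1_single_bearing", "H2_condition_dependent",
              "H3_context_dependent", "H4_mixed")

_M_PER_DEG_LAT = 111_320.0


@dataclass
class SimConfig:
    """Generative parameters for a synthetic cohort.

    Speed defaults anchor the observed ontogeny (0.45 cm/s at 2 dph rising
    to 0.62 cm/s at 30 dph); the turning-jitter SD declines with age to
    produce the straightening trend. Current speed defaults to the mean
    drift measured at deployment depth (4.38 cm/s).
    """

    n_larvae: int = 120
    seed: int = 0
    strategy: str = "H4_mixed"

    # strategy parameters
    goal_bearing_deg: float = 270.0            # H1: common goal (toward the reef)
    h2_early_goal_deg: float = 90.0            # H2: east early ...
    h2_switch_age_dph: int = 16                # ... flips 180° at this age
    h4_goals_deg: tuple = (90.0, 270.0)        # H4: mixture of retentive/dispersive goals
    h4_weights: tuple = (0.5, 0.5)
    arena_fixed_fraction: float = 0.0          # fraction of device-biased larvae
    goal_frame: str = "cardinal"               # "cardinal" or "arena" for the whole cohort

    # movement model
    kappa_goal: float = 2.0
    persistence_weight: float = 0.5
    speed_intercept_cm_s: float = 0.4379       # speed(age) = a + b*age
    speed_slope_cm_s_per_dph: float = 0.00607
    speed_noise_sd_cm_s: float = 0.1
    turning_sd_intercept_deg: float = 60.0     # jitter SD(age) = max(min, a + b*age)
    turning_sd_slope_deg_per_dph: float = -0.9
    turning_sd_min_deg: float = 25.0

    # arena and trial
    arena_radius_cm: float = 10.0
    trial_s: float = 900.0
    acclimation_s: float = 300.0
    dt_s: float = 1.0

    # chamber rotation
    # Net rotation near an integer multiple of 360° over the acquisition
    # window exactly cancels the cardinal-frame signature of an arena-fixed
    # attractor, making device bias unidentifiable; the default gives 225°.
    rotation_mode: str = "constant"            # "constant" or "random_walk"
    rotation_rate_deg_s: float = 0.25
    rotation_jitter_sd_deg: float = 0.0

    # site, drift and metadata
    natal_reef_lat: float = 16.8130
    natal_reef_lon: float = -88.0810
    reef_line_half_length_m: float = 325.0     # N-S transect through the reef midpoint
    deployment_offshore_m: float = 500.0       # east of the reef
    deployment_scatter_m: float = 150.0
    current_speed_cm_s: float = 4.38
    current_dir_deg: float = 200.0             # direction-toward
    gps_fix_interval_s: float = 60.0
    gps_jitter_sd_m: float = 3.0
    wind_dir_deg: float | None = None          # None: random per deployment

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")
        if self.kappa_goal < 0:
            raise ValueError("kappa_goal must be >= 0")
        if not 0.0 <= self.persistence_weight <= 1.0:
            raise ValueError("persistence_weight must be in [0, 1]")
        if not 0.0 <= self.arena_fixed_fraction <= 1.0:
            raise ValueError("arena_fixed_fraction must be in [0, 1]")
        if self.goal_frame not in ("cardinal", "arena"):
            raise ValueError("goal_frame must be 'cardinal' or 'arena'")
        if len(self.h4_goals_deg) != len(self.h4_weights):
            raise ValueError("h4_goals_deg and h4_weights must have equal length")
        n_steps = (self.acclimation_s + self.trial_s) / self.dt_s
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("dt_s must divide acclimation_s + trial_s")

    def speed_mean(self, age_dph: float) -> float:
        return max(0.0, self.speed_intercept_cm_s + self.speed_slope_cm_s_per_dph * age_dph)

    def turning_sd_deg(self, age_dph: float) -> float:
        return max(
            self.turning_sd_min_deg,
            self.turning_sd_intercept_deg + self.turning_sd_slope_deg_per_dph * age_dph,
        )

    def ages(self) -> np.ndarray:
        """Round-robin assignment over 2–30 dph by 2 (8 per age at n=120)."""
        base = np.arange(2, 31, 2)
        reps = int(np.ceil(self.n_larvae / base.size))
        return np.tile(base, reps)[: self.n_larvae]


@dataclass
class Truth:
    """Generative ground truth for one deployment."""

    strategy: str
    goal_bearing_deg: float | None   # in goal_frame coordinates; None for H0
    goal_frame: str                  # "cardinal" or "arena"
    age_dph: int
    kappa_goal: float
    speed_mean_cm_s: float
    turning_sd_deg: float


@dataclass
class SimulatedDeployment:
    trajectory: Trajectory
    compass: CompassSeries
    context: DeploymentContext
    truth: Truth


def _offset_latlon(lat: float, lon: float, east_m: float, north_m: float) -> tuple[float, float]:
    return (
        lat + north_m / _M_PER_DEG_LAT,
        lon + east_m / (_M_PER_DEG_LAT * math.cos(math.radians(lat))),
    )


def _goal_for(config: SimConfig, age: int, start_lat: float, start_lon: float,
              rng: np.random.Generator) -> float | None:
    s = config.strategy
    if s == "H0_none":
        return None
    if s == "H1_single_bearing":
        return config.goal_bearing_deg % 360.0
    if s == "H2_condition_dependent":
        g = config.h2_early_goal_deg
        if age >= config.h2_switch_age_dph:
            g += 180.0
        return g % 360.0
    if s == "H3_context_dependent":
        # nearest point of the N-S reef line: same latitude, clipped to the segment
        half_deg = config.reef_line_half_length_m / _M_PER_DEG_LAT
        lat_n = min(max(start_lat, config.natal_reef_lat - half_deg),
                    config.natal_reef_lat + half_deg)
        return initial_bearing(start_lat, start_lon, lat_n, config.natal_reef_lon)
    # H4_mixed
    w = np.asarray(config.h4_weights, dtype=float)
    return float(rng.choice(np.asarray(config.h4_goals_deg, dtype=float), p=w / w.sum()))


def _chamber_heading_deg(config: SimConfig, n_points: int, rng: np.random.Generator) -> np.ndarray:
    h0 = rng.uniform(0.0, 360.0)
    if config.rotation_mode == "constant":
        return h0 + config.rotation_rate_deg_s * config.dt_s * np.arange(n_points)
    if config.rotation_mode == "random_walk":
        steps = rng.normal(config.rotation_rate_deg_s * config.dt_s,
                           config.rotation_jitter_sd_deg, n_points - 1)
        return h0 + np.concatenate([[0.0], np.cumsum(steps)])
    raise ValueError(f"unknown rotation_mode {config.rotation_mode!r}")


def _walk(config: SimConfig, rng: np.random.Generator, age: int,
          goal_deg: float | None, goal_frame: str,
          heading_chamber_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """World-frame positions of the biased correlated random walk."""
    n_steps = heading_chamber_deg.size - 1
    dt = config.dt_s
    radius = config.arena_radius_cm
    w = config.persistence_weight

    kappa = config.kappa_goal if goal_deg is not None else 0.0
    if kappa > 0:
        eps = rng.vonmises(0.0, kappa, n_steps)
    else:
        eps = rng.uniform(-math.pi, math.pi, n_steps)
    jitter = rng.normal(0.0, math.radians(config.turning_sd_deg(age)), n_steps)
    if config.speed_noise_sd_cm_s > 0:
        steps_len = np.clip(
            rng.normal(config.speed_mean(age), config.speed_noise_sd_cm_s, n_steps), 0.0, None
        ) * dt
    else:
        steps_len = np.full(n_steps, config.speed_mean(age) * dt)

    if goal_deg is None:
        goal_world = None
    elif goal_frame == "arena":
        goal_world = np.deg2rad(goal_deg + heading_chamber_deg[:-1])
    else:
        goal_world = np.full(n_steps, math.radians(goal_deg))

    # uniform start position in the disc
    rho0 = radius * math.sqrt(rng.uniform())
    th0 = rng.uniform(0.0, 2 * math.pi)
    x, y = rho0 * math.sin(th0), rho0 * math.cos(th0)
    heading = rng.uniform(0.0, 2 * math.pi)
    sh, ch = math.sin(heading), math.cos(heading)

    xs = np.empty(n_steps + 1)
    ys = np.empty(n_steps + 1)
    xs[0], ys[0] = x, y
    sin, cos, atan2, hypot = math.sin, math.cos, math.atan2, math.hypot
    for i in range(n_steps):
        if goal_world is None:
            mu = heading
        else:
            g = goal_world[i]
            mu = atan2(w * sh + (1 - w) * sin(g), w * ch + (1 - w) * cos(g))
        heading = mu + eps[i] + jitter[i]
        sh, ch = sin(heading), cos(heading)
        x += steps_len[i] * sh
        y += steps_len[i] * ch
        rho = hypot(x, y)
        if rho > radius:
            f = (2.0 * radius - rho) / rho  # reflect radially off the wall
            if f < 0.0:
                f = radius / rho
            x *= f
            y *= f
        xs[i + 1], ys[i + 1] = x, y
    return xs, ys


_DEPLOY_START = datetime(2016, 5, 1, tzinfo=timezone.utc)
_LOCAL_UTC_OFFSET_H = 6  # site is UTC-6; deployments avoid the local noon window
_DEPLOY_HOURS_LOCAL = (7, 8, 9, 10, 11, 14, 15, 16, 17)


def _context(config: SimConfig, deployment_id: str, age: int,
             rng: np.random.Generator) -> DeploymentContext:
    east = config.deployment_offshore_m + rng.normal(0.0, config.deployment_scatter_m)
    north = rng.normal(0.0, config.deployment_scatter_m)
    lat, lon = _offset_latlon(config.natal_reef_lat, config.natal_reef_lon, east, north)
    day = int(rng.integers(0, 120))
    hour_local = int(rng.choice(_DEPLOY_HOURS_LOCAL))
    minute = int(rng.integers(0, 60))
    start = _DEPLOY_START + timedelta(days=day, hours=hour_local + _LOCAL_UTC_OFFSET_H,
                                      minutes=minute)
    wind = config.wind_dir_deg if config.wind_dir_deg is not None else rng.uniform(0.0, 360.0)

    # drifting float: start + current advection + per-fix GPS jitter
    v = config.current_speed_cm_s / 100.0  # m/s
    az = math.radians(config.current_dir_deg)
    total = config.acclimation_s + config.trial_s
    track = []
    t = 0.0
    while t <= total + 1e-9:
        east_t = v * t * math.sin(az) + rng.normal(0.0, config.gps_jitter_sd_m)
        north_t = v * t * math.cos(az) + rng.normal(0.0, config.gps_jitter_sd_m)
        fla, flo = _offset_latlon(lat, lon, east_t, north_t)
        track.append((start + timedelta(seconds=t), fla, flo))
        t += config.gps_fix_interval_s
    return DeploymentContext(
        deployment_id=deployment_id,
        start_utc=start,
        lat=lat,
        lon=lon,
        natal_reef_lat=config.natal_reef_lat,
        natal_reef_lon=config.natal_reef_lon,
        wind_dir_deg=wind % 360.0,
        gps_track=track,
        age_dph=age,
    )


def simulate_trajectory(config: SimConfig, larva_index: int) -> SimulatedDeployment:
    """Simulate one deployment; fully determined by (config.seed, larva_index)."""
    if not 0 <= larva_index < config.n_larvae:
        raise ValueError(f"larva_index {larva_index} outside [0, {config.n_larvae})")
    rng = np.random.default_rng([config.seed, larva_index])
    age = int(config.ages()[larva_index])
    deployment_id = f"sim{larva_index:04d}"

    context = _context(config, deployment_id, age, rng)
    goal = _goal_for(config, age, context.lat, context.lon, rng)
    goal_frame = config.goal_frame
    if goal is not None and config.arena_fixed_fraction > 0:
        if rng.uniform() < config.arena_fixed_fraction:
            goal_frame = "arena"
            goal = rng.uniform(0.0, 360.0)  # the chamber feature it fixates on

    n_points = int(round((config.acclimation_s + config.trial_s) / config.dt_s)) + 1
    heading_chamber = _chamber_heading_deg(config, n_points, rng)
    xs_world, ys_world = _walk(config, rng, age, goal, goal_frame, heading_chamber)

    # record what the camera sees: world positions counter-rotated by the chamber
    theta_world = np.arctan2(xs_world, ys_world)
    rho = np.hypot(xs_world, ys_world)
    theta_cam = theta_world - np.deg2rad(heading_chamber)
    t = np.arange(n_points) * config.dt_s
    trajectory = Trajectory(
        deployment_id=deployment_id,
        t=t,
        x=rho * np.sin(theta_cam),
        y=rho * np.cos(theta_cam),
        arena_radius_cm=config.arena_radius_cm,
        acclimation_s=config.acclimation_s,
    )
    compass = CompassSeries(t=t.copy(), heading_deg=heading_chamber % 360.0,
                            deployment_id=deployment_id)
    truth = Truth(
        strategy=config.strategy,
        goal_bearing_deg=goal,
        goal_frame=goal_frame,
        age_dph=age,
        kappa_goal=config.kappa_goal if goal is not None else 0.0,
        speed_mean_cm_s=config.speed_mean(age),
        turning_sd_deg=config.turning_sd_deg(age),
    )
    return SimulatedDeployment(trajectory, compass, context, truth)


def simulate_cohort(config: SimConfig) -> tuple[list[SimulatedDeployment], pd.DataFrame]:
    """Simulate the whole cohort; returns deployments and a truth table."""
    deployments = [simulate_trajectory(config, i) for i in range(config.n_larvae)]
    truth = pd.DataFrame(
        [
            {
                "deployment_id": d.trajectory.deployment_id,
                **asdict(d.truth),
            }
            for d in deployments
        ]
    )
    return deployments, truth


def write_cohort(deployments: list[SimulatedDeployment], truth: pd.DataFrame,
                 out_dir, config: SimConfig) -> None:
    """Emit a complete runnable cohort directory in the analysis CSV dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_trajectories_csv([d.trajectory for d in deployments], out / "trajectories.csv")
    write_compass_csv([d.compass for d in deployments], out / "compass.csv")
    meta = pd.DataFrame(
        [
            {
                "deployment_id": d.context.deployment_id,
                "start_utc": d.context.start_utc.isoformat(),
                "lat": d.context.lat,
                "lon": d.context.lon,
                "wind_dir_deg": d.context.wind_dir_deg,
                "age_dph": d.context.age_dph,
            }
            for d in deployments
        ]
    )
    meta.to_csv(out / "metadata.csv", index=False)
    gps = pd.concat(
        [
            pd.DataFrame(
                {
                    "deployment_id": d.context.deployment_id,
                    "utc": [fx[0].isoformat() for fx in d.context.gps_track],
                    "lat": [fx[1] for fx in d.context.gps_track],
                    "lon": [fx[2] for fx in d.context.gps_track],
                }
            )
            for d in deployments
        ],
        ignore_index=True,
    )
    gps.to_csv(out / "gps.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    with open(out / "config.cfg", "w") as fh:
        fh.write("# site constants consumed by the analysis pipeline\n")
        fh.write(f"natal_reef_lat = {config.natal_reef_lat}\n")
        fh.write(f"natal_reef_lon = {config.natal_reef_lon}\n")
        fh.write(f"arena_radius_cm = {config.arena_radius_cm}\n")
        fh.write(f"acclimation_s = {config.acclimation_s}\n")
        fh.write("alpha = 0.05\n")
        fh.write("rotation_sign = 1\n")
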