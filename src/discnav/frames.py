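"""Frame-of-reference correction and device-bias screening.

The chamber rotates slowly as it drifts, so bearings measured in the video
(camera frame) must be rotated by the synchronized compass heading to obtain
cardinal (geographic) bearings. Comparing the concentration of a larva's
positions in the two frames separates artifactual attraction to a chamber
component (tighter in the camera frame) from genuine orientation to a
cardinal direction (tighter in the cardinal frame).

Sign convention: cardinal = camera + heading, where the heading is the
compass direction the camera-frame "up" axis points to. Real chambers wired
the other way can be ingested with ``rotation_sign=-1``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circstats import AngleSample, circular_mean_and_r, rayleigh_test
from .kinematics import Trajectory, position_bearings

log = logging.getLogger(__name__)

__all__ = [
    "CompassSeries",
    "FrameAnalysis",
    "NON_ORIENTED",
    "DEVICE_BIASED",
    "ORIENTED",
    "rotate_to_cardinal",
    "classify_deployment",
    "merge_compasses",
    "read_compass_csv",
    "write_compass_csv",
]

NON_ORIENTED = "non_oriented"
DEVICE_BIASED = "device_biased"
ORIENTED = "oriented"

#: largest tolerated gap (s) between a bearing and its nearest compass sample
MAX_COMPASS_GAP_S = 2.0


@dataclass
class CompassSeries:
    """Chamber heading vs time for one deployment.

    heading_deg is degrees clockwise from north in [0, 360); t is seconds
    from acquisition start, strictly increasing.
    """

    t: np.ndarray
    heading_deg: np.ndarray
    deployment_id: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.heading_deg = np.asarray(self.heading_deg, dtype=float) % 360.0
        if self.t.shape != self.heading_deg.shape:
            raise ValueError(f"{self.deployment_id}: compass t/heading length mismatch")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError(f"{self.deployment_id}: compass timestamps not strictly increasing")

    def heading_at(self, times) -> np.ndarray:
        """Nearest-neighbor heading lookup; errors on gaps over 2 s."""
        times = np.asarray(times, dtype=float)
        idx = np.clip(np.searchsorted(self.t, times), 1, self.t.size - 1)
        left, right = self.t[idx - 1], self.t[idx]
        use_left = (times - left) <= (right - times)
        nearest = np.where(use_left, idx - 1, idx)
        gap = np.abs(times - self.t[nearest])
        if np.any(gap > MAX_COMPASS_GAP_S):
            i = int(np.argmax(gap))
            raise ValueError(
                f"{self.deployment_id}: compass gap of {gap[i]:.1f} s at t={times[i]:.1f} s "
                f"exceeds {MAX_COMPASS_GAP_S} s"
            )
        return self.heading_deg[nearest]


@dataclass
class FrameAnalysis:
    """Camera- vs cardinal-frame comparison for one deployment."""

    deployment_id: str
    rho_camera: float
    rho_cardinal: float
    bearing_cardinal_deg: float
    p_cardinal: float
    classification: str
    n: int


def rotate_to_cardinal(
    bearings_camera: AngleSample,
    times,
    compass: CompassSeries,
    rotation_sign: int = 1,
) -> AngleSample:
    """Rotate camera-frame bearings into the cardinal frame per timestamp."""
    heading = compass.heading_at(times)
    return AngleSample(
        (bearings_camera.angles_deg + rotation_sign * heading) % 360.0,
        label=f"{bearings_camera.label or compass.deployment_id} cardinal".strip(),
    )


def classify_deployment(
    traj: Trajectory,
    compass: CompassSeries,
    alpha: float = 0.05,
    rotation_sign: int = 1,
) -> FrameAnalysis:
    """Classify one deployment as non-oriented, device-biased or oriented.

    Position bearings are tested for uniformity in the cardinal frame
    (Rayleigh). Non-significant deployments are non_oriented. Among
    significant ones, a larva whose positions are *more* concentrated in the
    rotating camera frame than in the cardinal frame was tracking a chamber
    feature, not a compass direction: device_biased. The rest are oriented.
    The measure-zero tie rho_camera == rho_cardinal counts as oriented
    (logged).
    """
    cam, t_used = position_bearings(traj)
    card = rotate_to_cardinal(cam, t_used, compass, rotation_sign=rotation_sign)
    _, rho_cam = circular_mean_and_r(cam)
    summary = rayleigh_test(card)
    if summary.p_value >= alpha:
        cls = NON_ORIENTED
    elif rho_cam > summary.r:
        cls = DEVICE_BIASED
    else:
        if rho_cam == summary.r:
            log.info("%s: rho tie between frames; classified oriented", traj.deployment_id)
        cls = ORIENTED
    return FrameAnalysis(
        deployment_id=traj.deployment_id,
        rho_camera=rho_cam,
        rho_cardinal=summary.r,
        bearing_cardinal_deg=summary.mean_bearing_deg,
        p_cardinal=summary.p_value,
        classification=cls,
        n=summary.n,
    )


def merge_compasses(series: list[CompassSeries]) -> CompassSeries:
    """Fuse redundant compass units into one series by circular mean.

    All series must share the same timestamps (the physical compasses are
    sampled by one logger).
    """
    if not series:
        raise ValueError("no compass series to merge")
    t0 = series[0].t
    for s in series[1:]:
        if s.t.shape != t0.shape or not np.allclose(s.t, t0):
            raise ValueError("compass series to merge must share timestamps")
    rad = np.deg2rad(np.vstack([s.heading_deg for s in series]))
    merged = np.degrees(np.arctan2(np.sin(rad).mean(axis=0), np.cos(rad).mean(axis=0))) % 360.0
    return CompassSeries(t=t0.copy(), heading_deg=merged, deployment_id=series[0].deployment_id)


def read_compass_csv(path) -> dict[str, CompassSeries]:
    """Read a multi-deployment compass table: deployment_id, t_s, heading_deg."""
    df = pd.read_csv(path)
    required = {"deployment_id", "t_s", "heading_deg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing compass columns {sorted(missing)}")
    out = {}
    for dep, g in df.groupby("deployment_id", sort=True):
        g = g.sort_values("t_s")
        out[str(dep)] = CompassSeries(
            t=g["t_s"].to_numpy(), heading_deg=g["heading_deg"].to_numpy(), deployment_id=str(dep)
        )
    return out


def write_compass_csv(series_list, path) -> None:
    frames = [
        pd.DataFrame(
            {"deployment_id": s.deployment_id, "t_s": s.t, "heading_deg": s.heading_deg}
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.4f")
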