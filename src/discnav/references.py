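"""Per-deployment reference directions and the orientation-goal hypothesis battery.

For each deployment we derive the compass directions a larva might be
orienting to: the sun azimuth at the trial midpoint, the great-circle bearing
to its natal reef, the direction of the ambient current (net drift of the
chamber's surface float), and the wind direction (direction-toward). The
battery then asks, hypothesis by hypothesis and age group by age group,
whether the retained larvae share a common bearing once each larva's mean
bearing is re-expressed relative to its own deployment's reference
(second-order Rayleigh test). The cardinal hypothesis uses the raw bearings.

Solar position follows the NOAA solar-calculator formulation (Meeus-class
series for the sun's ecliptic longitude, declination and the equation of
time); azimuth accuracy is a few hundredths of a degree away from the poles,
ample for a cue whose behavioral use is tested at tens of degrees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np

from .circstats import AngleSample, CircularSummary, relative_bearings, second_order_rayleigh

log = logging.getLogger(__name__)

__all__ = [
    "DeploymentContext",
    "HypothesisResult",
    "DriftEstimate",
    "HYPOTHESES",
    "AGE_GROUPS",
    "sun_position",
    "sun_azimuth",
    "initial_bearing",
    "haversine_m",
    "drift_direction_and_speed",
    "reference_direction",
    "hypothesis_battery",
]

HYPOTHESES = ("cardinal", "current", "wind", "sun_azimuth", "natal_reef")

#: developmental age groups (days post-hatch): pre-flexion, post-flexion, pre-settlement
AGE_GROUPS = (("2-10", 2, 10), ("12-20", 12, 20), ("22-30", 22, 30))

EARTH_RADIUS_M = 6371008.8  # mean radius

#: net float displacement below this (m) gives an unreliable drift direction
GPS_NOISE_FLOOR_M = 5.0


@dataclass
class DeploymentContext:
    """Where and when one deployment happened, plus its environmental cues."""

    deployment_id: str
    start_utc: datetime
    lat: float
    lon: float
    natal_reef_lat: float
    natal_reef_lon: float
    wind_dir_deg: float  # direction-toward, deg CW from north
    gps_track: list[tuple[datetime, float, float]] = field(default_factory=list)
    age_dph: int = -1

    def __post_init__(self) -> None:
        if abs(self.lat) > 90:
            raise ValueError(f"{self.deployment_id}: |lat| > 90")
        self.lon = ((self.lon + 180.0) % 360.0) - 180.0
        if self.lon == -180.0:
            self.lon = 180.0
        if self.gps_track:
            times = [fx[0] for fx in self.gps_track]
            if any(b <= a for a, b in zip(times, times[1:])):
                raise ValueError(f"{self.deployment_id}: GPS fix timestamps not increasing")


@dataclass
class HypothesisResult:
    hypothesis: str
    age_group: str
    summary: CircularSummary


@dataclass
class DriftEstimate:
    direction_deg: float
    speed_cm_s: float
    reliable: bool
    displacement_m: float


# --- solar position (NOAA solar calculator / Meeus-class series) ---------

def _julian_day(when: datetime) -> float:
    if when.tzinfo is None:
        when = when.replace(tzinfo=timezone.utc)
    when = when.astimezone(timezone.utc)
    y, m = when.year, when.month
    d = (
        when.day
        + (when.hour + when.minute / 60.0 + when.second / 3600.0 + when.microsecond / 3.6e9)
        / 24.0
    )
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def sun_position(lat: float, lon: float, when_utc: datetime) -> tuple[float, float]:
    """Solar (azimuth, elevation) in degrees; azimuth CW from north.

    Atmospheric refraction is not applied: the azimuth, the quantity used as
    an orientation cue, is unaffected by refraction, and elevation is only
    used as an above-horizon flag.
    """
    jc = (_julian_day(when_utc) - 2451545.0) / 36525.0
    l0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    m = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    mr = math.radians(m)
    c = (
        math.sin(mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * mr) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * mr) * 0.000289
    )
    true_long = l0 + c
    omega = math.radians(125.04 - 1934.136 * jc)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    e0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    eps = math.radians(e0 + 0.00256 * math.cos(omega))
    lam = math.radians(app_long)
    decl = math.asin(math.sin(eps) * math.sin(lam))
    y = math.tan(eps / 2.0) ** 2
    l0r = math.radians(l0)
    eqtime_min = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2 * ecc * math.sin(mr)
        + 4 * ecc * y * math.sin(mr) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * ecc * ecc * math.sin(2 * mr)
    )
    if when_utc.tzinfo is None:
        when_utc = when_utc.replace(tzinfo=timezone.utc)
    ut = when_utc.astimezone(timezone.utc)
    minutes_utc = ut.hour * 60 + ut.minute + ut.second / 60.0 + ut.microsecond / 6e7
    tst = (minutes_utc + eqtime_min + 4.0 * lon) % 1440.0
    ha = math.radians(tst / 4.0 - 180.0)
    phi = math.radians(lat)
    cos_zen = math.sin(phi) * math.sin(decl) + math.cos(phi) * math.cos(decl) * math.cos(ha)
    cos_zen = max(-1.0, min(1.0, cos_zen))
    elevation = 90.0 - math.degrees(math.acos(cos_zen))
    az = (
        math.degrees(
            math.atan2(
                math.sin(ha), math.cos(ha) * math.sin(phi) - math.tan(decl) * math.cos(phi)
            )
        )
        + 180.0
    ) % 360.0
    return az, elevation


def sun_azimuth(lat: float, lon: float, when_utc: datetime) -> float:
    """Solar azimuth, degrees CW from north; logs a flag if the sun is set."""
    az, elev = sun_position(lat, lon, when_utc)
    if elev < 0:
        log.warning(
            "sun below horizon (elevation %.1f°) at %s for (%.3f, %.3f); azimuth %.1f° returned",
            elev, when_utc, lat, lon, az,
        )
    return az


# --- great-circle geodesy -------------------------------------------------

def initial_bearing(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Initial great-circle bearing from point 1 to point 2, deg CW from north."""
    if lat1 == lat2 and (lon1 - lon2) % 360.0 == 0.0:
        raise ValueError("bearing undefined between identical points")
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    x = math.sin(dl) * math.cos(p2)
    y = math.cos(p1) * math.sin(p2) - math.sin(p1) * math.cos(p2) * math.cos(dl)
    return math.degrees(math.atan2(x, y)) % 360.0


def haversine_m(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance on the mean-radius sphere, meters."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dl = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
    return 2 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))


def drift_direction_and_speed(
    gps_track: list[tuple[datetime, float, float]],
    noise_floor_m: float = GPS_NOISE_FLOOR_M,
) -> DriftEstimate:
    """Current direction and speed from the float's net displacement.

    Direction is the initial bearing from the first to the last fix of the
    window; speed is great-circle distance over elapsed time, cm/s. Net
    displacement is robust to per-fix GPS jitter; tracks whose net
    displacement falls below the noise floor get an unreliable flag.
    """
    if len(gps_track) < 2:
        raise ValueError("drift estimate needs at least 2 GPS fixes")
    (t0, la0, lo0), (t1, la1, lo1) = gps_track[0], gps_track[-1]
    elapsed = (t1 - t0).total_seconds()
    if elapsed <= 0:
        raise ValueError("GPS fixes must span positive time")
    disp = haversine_m(la0, lo0, la1, lo1)
    if disp < noise_floor_m:
        log.warning(
            "net float displacement %.1f m below noise floor %.1f m; direction unreliable",
            disp, noise_floor_m,
        )
        direction = float("nan") if disp == 0.0 else initial_bearing(la0, lo0, la1, lo1)
        return DriftEstimate(direction, disp * 100.0 / elapsed, False, disp)
    return DriftEstimate(
        initial_bearing(la0, lo0, la1, lo1), disp * 100.0 / elapsed, True, disp
    )


# --- reference directions and the hypothesis battery ----------------------

def reference_direction(
    context: DeploymentContext,
    hypothesis: str,
    trial_midpoint_offset_s: float = 750.0,
) -> float | None:
    """Reference bearing for one deployment under one hypothesis.

    Sun azimuth is evaluated at the trial midpoint (default 750 s after
    start: half-way through a 5 min acclimation + 15 min acquisition trial).
    Returns None where the reference is undefined/unreliable (e.g. a
    stagnant drift track), so the caller can drop the larva from that
    hypothesis only.
    """
    if hypothesis == "cardinal":
        return 0.0
    if hypothesis == "wind":
        return context.wind_dir_deg % 360.0
    if hypothesis == "sun_azimuth":
        from datetime import timedelta

        return sun_azimuth(
            context.lat, context.lon, context.start_utc + timedelta(seconds=trial_midpoint_offset_s)
        )
    if hypothesis == "natal_reef":
        return initial_bearing(
            context.lat, context.lon, context.natal_reef_lat, context.natal_reef_lon
        )
    if hypothesis == "current":
        if len(context.gps_track) < 2:
            log.warning("%s: no usable GPS track; current reference undefined", context.deployment_id)
            return None
        est = drift_direction_and_speed(context.gps_track)
        return est.direction_deg if est.reliable else None
    raise ValueError(f"unknown hypothesis {hypothesis!r}")


def _battery_cell(
    hypothesis: str, group_label: str, bearings: list[float], refs: list[float]
) -> HypothesisResult | None:
    if len(bearings) < 2:
        log.info("battery: %s / %s omitted (n=%d < 2)", hypothesis, group_label, len(bearings))
        return None
    sample = AngleSample(np.asarray(bearings), label=f"{hypothesis} {group_label}")
    if hypothesis != "cardinal":
        sample = relative_bearings(sample, np.asarray(refs))
    return HypothesisResult(hypothesis, group_label, second_order_rayleigh(sample))


def hypothesis_battery(
    results,
    contexts: dict[str, DeploymentContext],
    age_groups=AGE_GROUPS,
) -> list[HypothesisResult]:
    """Run the full hypothesis x age-group grid of second-order Rayleigh tests.

    ``results`` are per-larva rows (only classification == "oriented" rows
    enter the tests); ``contexts`` maps deployment_id to its
    DeploymentContext. For the cardinal hypothesis the raw cardinal mean
    bearings are pooled; for each cue hypothesis every larva's mean bearing
    is first expressed relative to its own deployment's reference, so
    clustering near 0° means the population follows that cue. Cells with
    fewer than two larvae (or whose references are all undefined) are
    omitted with a log entry.
    """
    oriented = [lr for lr in results if lr.classification == "oriented"]
    out: list[HypothesisResult] = []
    for hyp in HYPOTHESES:
        pairs = []
        for lr in oriented:
            ctx = contexts.get(lr.deployment_id)
            if ctx is None:
                log.warning("battery: no context for %s; dropped from %s", lr.deployment_id, hyp)
                continue
            ref = reference_direction(ctx, hyp)
            if ref is None:
                continue
            pairs.append((lr.age_dph, lr.bearing_cardinal_deg, ref))
        cell = _battery_cell(
            hyp, "all", [b for _, b, _ in pairs], [r for _, _, r in pairs]
        )
        if cell:
            out.append(cell)
        for label, lo, hi in age_groups:
            sub = [(b, r) for a, b, r in pairs if lo <= a <= hi]
            cell = _battery_cell(hyp, label, [b for b, _ in sub], [r for _, r in sub])
            if cell:
                out.append(cell)
    return out
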