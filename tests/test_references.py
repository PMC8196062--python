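"""Solar azimuth, great-circle geodesy, drift estimation, hypothesis battery."""

import math
from datetime import datetime, timedelta, timezone

import numpy as np
import pytest

from discnav.circstats import AngleSample, second_order_rayleigh
from discnav.ontogeny import LarvaResult
from discnav.references import (
    AGE_GROUPS,
    DeploymentContext,
    drift_direction_and_speed,
    haversine_m,
    hypothesis_battery,
    initial_bearing,
    reference_direction,
    sun_azimuth,
    sun_position,
    _julian_day,
)

SITE = (16.813, -88.081)


def michalsky_azimuth(lat, lon, when):
    """Independent low-precision solar ephemeris (Astronomical Almanac
    formulation) used as an oracle for the packaged algorithm."""
    when = when.astimezone(timezone.utc)
    n = _julian_day(when) - 2451545.0
    big_l = (280.460 + 0.9856474 * n) % 360
    g = math.radians((357.528 + 0.9856003 * n) % 360)
    lam = math.radians(big_l + 1.915 * math.sin(g) + 0.020 * math.sin(2 * g))
    eps = math.radians(23.439 - 0.0000004 * n)
    ra = math.atan2(math.cos(eps) * math.sin(lam), math.cos(lam))
    dec = math.asin(math.sin(eps) * math.sin(lam))
    ut = when.hour + when.minute / 60 + when.second / 3600
    gmst = (6.697375 + 0.0657098242 * (n - ut / 24) + 1.00273790935 * ut) % 24
    lmst = (gmst + lon / 15) % 24
    ha = math.radians(((lmst * 15 - math.degrees(ra)) + 180) % 360 - 180)
    phi = math.radians(lat)
    return (
        math.degrees(
            math.atan2(math.sin(ha), math.cos(ha) * math.sin(phi) - math.tan(dec) * math.cos(phi))
        )
        + 180.0
    ) % 360.0


class TestSunAzimuth:
    def test_solar_noon_tropics_winter_is_south(self):
        # local solar noon at 88.1°W is ~17:52 UTC; northern-tropics sun due south
        az = sun_azimuth(16.8, -88.1, datetime(2016, 12, 21, 17, 52, tzinfo=timezone.utc))
        assert az == pytest.approx(180.0, abs=1.0)

    def test_equinox_sunrise_equator_is_east(self):
        az, elev = sun_position(0.0, 0.0, datetime(2016, 3, 20, 6, 0, tzinfo=timezone.utc))
        assert az == pytest.approx(90.0, abs=1.0)
        assert abs(elev) < 3.0

    def test_study_site_case_matches_independent_ephemeris(self):
        when = datetime(2016, 6, 15, 14, 0, tzinfo=timezone.utc)
        az = sun_azimuth(16.8, -88.1, when)
        assert az == pytest.approx(michalsky_azimuth(16.8, -88.1, when), abs=0.5)
        assert az == pytest.approx(72.94, abs=0.5)  # frozen oracle value

    def test_agrees_with_independent_ephemeris_over_a_year(self):
        worst = 0.0
        for day in range(0, 360, 23):
            for hour in (13, 16, 20, 23):
                when = datetime(2016, 1, 5, tzinfo=timezone.utc) + timedelta(days=day, hours=hour)
                a1, _ = sun_position(*SITE, when)
                a2 = michalsky_azimuth(*SITE, when)
                worst = max(worst, abs((a1 - a2 + 180) % 360 - 180))
        assert worst < 0.5

    def test_below_horizon_flagged_but_returned(self, caplog):
        midnight_local = datetime(2016, 6, 15, 6, 0, tzinfo=timezone.utc)
        with caplog.at_level("WARNING", logger="discnav.references"):
            az = sun_azimuth(*SITE, midnight_local)
        assert 0.0 <= az < 360.0
        assert "below horizon" in caplog.text

    def test_monotone_through_midday_when_sun_transits_south(self):
        # with declination below the site latitude the sun transits to the
        # south and azimuth advances monotonically through the daylight
        # window (near the June solstice the declination exceeds 16.8°N and
        # the azimuth develops turning points, so monotonicity is seasonal)
        azs = [
            sun_azimuth(*SITE, datetime(2016, 3, 15, 13, 0, tzinfo=timezone.utc)
                        + timedelta(minutes=30 * k))
            for k in range(20)
        ]
        diffs = np.diff(np.unwrap(np.radians(azs)))
        assert np.all(diffs > 0)


# (lat1, lon1, lat2, lon2, bearing_deg, distance_m) frozen from R geosphere
# bearing(p1, p2, f=0) / distHaversine(r=6371008.8): great circle on a sphere
GEODESIC_ORACLE = [
    (28.3905977570, 141.0340547888, -3.0003502127, 147.7885640319, 167.2143966914, 3564400.949),
    (-43.8400083315, 148.6056405213, 7.2399295494, -83.1541997241, 113.2282279216, 13567698.105),
    (18.8390748482, -72.7125581726, 48.4837664757, -12.8204403352, 43.6401821670, 6247827.518),
    (24.6077740844, 112.3521928629, -43.3547798730, 149.6049377369, 153.0355688342, 8461247.718),
    (-5.0709868502, 48.1934764236, 58.6670074705, 162.5969856512, 29.6525422737, 11878790.886),
    (26.2934701983, 6.4926227042, 53.6001879070, -130.0542970374, 335.9014157469, 10196608.045),
]


class TestGeodesy:
    def test_due_north_is_zero(self):
        assert initial_bearing(16.80, -88.08, 16.81, -88.08) == pytest.approx(0.0, abs=1e-9)

    def test_due_east_on_equator_is_90(self):
        assert initial_bearing(0.0, 10.0, 0.0, 11.0) == pytest.approx(90.0, abs=1e-9)

    def test_identical_points_rejected(self):
        with pytest.raises(ValueError):
            initial_bearing(1.0, 2.0, 1.0, 2.0)

    @pytest.mark.parametrize("lat1, lon1, lat2, lon2, bearing, dist", GEODESIC_ORACLE)
    def test_matches_geodesic_library_oracle(self, lat1, lon1, lat2, lon2, bearing, dist):
        assert initial_bearing(lat1, lon1, lat2, lon2) == pytest.approx(bearing, abs=0.1)
        assert haversine_m(lat1, lon1, lat2, lon2) == pytest.approx(dist, rel=0.002)


class TestDrift:
    def test_known_southward_drift(self):
        t0 = datetime(2016, 6, 1, 14, 0, tzinfo=timezone.utc)
        lat0, lon0 = 16.81, -88.07
        lat1 = lat0 - 100.0 / 111_320.0  # 100 m due south
        est = drift_direction_and_speed([(t0, lat0, lon0), (t0 + timedelta(seconds=1000), lat1, lon0)])
        assert est.direction_deg == pytest.approx(180.0, abs=0.1)
        assert est.speed_cm_s == pytest.approx(10.0, rel=0.002)
        assert est.reliable

    def test_stationary_track_flagged(self):
        t0 = datetime(2016, 6, 1, 14, 0, tzinfo=timezone.utc)
        est = drift_direction_and_speed(
            [(t0, 16.81, -88.07), (t0 + timedelta(seconds=900), 16.81, -88.07)]
        )
        assert not est.reliable

    def test_jittered_constant_drift_recovered(self, rng):
        t0 = datetime(2016, 6, 1, 14, 0, tzinfo=timezone.utc)
        v, az = 0.05, math.radians(230.0)  # 5 cm/s toward 230°
        track = []
        for k in range(16):
            t = 60.0 * k
            east = v * t * math.sin(az) + rng.normal(0, 3.0)
            north = v * t * math.cos(az) + rng.normal(0, 3.0)
            track.append(
                (t0 + timedelta(seconds=t),
                 16.81 + north / 111_320.0,
                 -88.07 + east / (111_320.0 * math.cos(math.radians(16.81)))))
        est = drift_direction_and_speed(track)
        assert est.reliable
        assert abs((est.direction_deg - 230.0 + 180) % 360 - 180) < 5.0


def make_context(dep_id, start, lat=16.813, lon=-88.0763, wind=140.0, age=10, track=()):
    return DeploymentContext(
        deployment_id=dep_id, start_utc=start, lat=lat, lon=lon,
        natal_reef_lat=16.8130, natal_reef_lon=-88.0810,
        wind_dir_deg=wind, gps_track=list(track), age_dph=age,
    )


def make_result(dep_id, age, bearing, classification="oriented"):
    return LarvaResult(
        deployment_id=dep_id, age_dph=age, mean_speed_cm_s=0.5, mean_turning_deg=45.0,
        classification=classification, bearing_cardinal_deg=bearing, rho=0.8,
        p_cardinal=0.001,
    )


class TestReferenceDirection:
    def test_wind_passthrough(self):
        ctx = make_context("d", datetime(2016, 6, 15, 14, 0, tzinfo=timezone.utc), wind=140.0)
        assert reference_direction(ctx, "wind") == pytest.approx(140.0)

    def test_natal_reef_is_westward_for_offshore_start(self):
        ctx = make_context("d", datetime(2016, 6, 15, 14, 0, tzinfo=timezone.utc))
        assert reference_direction(ctx, "natal_reef") == pytest.approx(270.0, abs=1.0)

    def test_unknown_hypothesis_rejected(self):
        ctx = make_context("d", datetime(2016, 6, 15, 14, 0, tzinfo=timezone.utc))
        with pytest.raises(ValueError):
            reference_direction(ctx, "magnetic")

    def test_unreliable_current_returns_none(self):
        t0 = datetime(2016, 6, 15, 14, 0, tzinfo=timezone.utc)
        ctx = make_context("d", t0, track=[(t0, 16.81, -88.07),
                                           (t0 + timedelta(seconds=900), 16.81, -88.07)])
        assert reference_direction(ctx, "current") is None


class TestHypothesisBattery:
    def _cohort(self, rng, n=40, follow_sun=False):
        results, contexts = [], {}
        base = datetime(2016, 5, 1, tzinfo=timezone.utc)
        for k in range(n):
            dep = f"d{k:03d}"
            start = base + timedelta(days=int(rng.integers(0, 120)),
                                     hours=int(rng.choice([13, 14, 15, 16, 17, 20, 21, 22, 23])),
                                     minutes=int(rng.integers(0, 60)))
            ctx = make_context(dep, start, age=int(rng.choice(np.arange(2, 31, 2))))
            if follow_sun:
                goal = sun_azimuth(ctx.lat, ctx.lon, start + timedelta(seconds=750))
            else:
                goal = 120.0
            bearing = (goal + math.degrees(rng.vonmises(0.0, 4.0))) % 360.0
            results.append(make_result(dep, ctx.age_dph, bearing))
            contexts[dep] = ctx
        return results, contexts

    def test_cardinal_reduces_to_second_order_on_raw_bearings(self, rng):
        results, contexts = self._cohort(rng)
        grid = hypothesis_battery(results, contexts)
        cardinal = next(g for g in grid if g.hypothesis == "cardinal" and g.age_group == "all")
        direct = second_order_rayleigh(
            AngleSample(np.array([r.bearing_cardinal_deg for r in results]))
        )
        assert cardinal.summary.r == pytest.approx(direct.r, abs=1e-12)
        assert cardinal.summary.p_value == pytest.approx(direct.p_value, abs=1e-12)

    def test_constant_reference_gives_same_p_as_cardinal(self, rng):
        # wind is constant across deployments here, so only the mean moves
        results, contexts = self._cohort(rng)
        grid = hypothesis_battery(results, contexts)
        cardinal = next(g for g in grid if g.hypothesis == "cardinal" and g.age_group == "all")
        wind = next(g for g in grid if g.hypothesis == "wind" and g.age_group == "all")
        assert wind.summary.p_value == pytest.approx(cardinal.summary.p_value, abs=1e-9)
        assert wind.summary.r == pytest.approx(cardinal.summary.r, abs=1e-12)

    def test_sun_following_cohort_detected_only_in_sun_frame(self, rng):
        results, contexts = self._cohort(rng, follow_sun=True)
        grid = hypothesis_battery(results, contexts)
        sun = next(g for g in grid if g.hypothesis == "sun_azimuth" and g.age_group == "all")
        cardinal = next(g for g in grid if g.hypothesis == "cardinal" and g.age_group == "all")
        assert sun.summary.p_value < 0.05
        assert abs((sun.summary.mean_bearing_deg + 180) % 360 - 180) < 15.0
        assert cardinal.summary.p_value > 0.05

    def test_only_oriented_larvae_enter(self, rng):
        results, contexts = self._cohort(rng, n=10)
        results[0] = make_result("d000", 10, 0.0, classification="device_biased")
        grid = hypothesis_battery(results, contexts)
        cardinal = next(g for g in grid if g.hypothesis == "cardinal" and g.age_group == "all")
        assert cardinal.summary.n == 9

    def test_single_larva_group_omitted(self):
        start = datetime(2016, 6, 15, 14, 0, tzinfo=timezone.utc)
        results = [make_result("a", 4, 10.0), make_result("b", 6, 30.0),
                   make_result("c", 24, 200.0)]
        contexts = {r.deployment_id: make_context(r.deployment_id, start, age=r.age_dph)
                    for r in results}
        grid = hypothesis_battery(results, contexts)
        groups = {g.age_group for g in grid if g.hypothesis == "cardinal"}
        assert "2-10" in groups
        assert "22-30" not in groups  # single larva: cell omitted

    def test_age_group_bins_match_study_design(self):
        assert AGE_GROUPS == (("2-10", 2, 10), ("12-20", 12, 20), ("22-30", 22, 30))
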