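"""Feature-extraction stack: geodesy, activity, movement, home, POI, screen."""

from __future__ import annotations

import math
from datetime import date as Date, timedelta

import numpy as np
import pandas as pd
import pytest

from phenotrack.config import PipelineConfig
from phenotrack.features import (
    EARTH_RADIUS_M,
    HomeLocation,
    activity_duration_ratio,
    compute_speeds,
    detect_poi,
    extract_daily_features,
    geodesic_distance,
    infer_home,
    mean_distance_to_home,
    minute_variances,
    movement_duration_ratio,
    normalize_accel,
    screen_time_ratio,
    time_at_home_ratio,
    two_week_means,
)
from phenotrack.sensor_io import local_day_window

M_PER_DEG = EARTH_RADIUS_M * math.pi / 180.0


# --------------------------------------------------------------------------
# geodesy


class TestGeodesicDistance:
    def test_identical_points_zero(self):
        assert geodesic_distance(54.9, 23.9, 54.9, 23.9) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(-80, 80, size=(20, 4))
        np.testing.assert_allclose(
            geodesic_distance(p[:, 0], p[:, 1], p[:, 2], p[:, 3]),
            geodesic_distance(p[:, 2], p[:, 3], p[:, 0], p[:, 1]),
        )

    def test_antipodal_half_circumference(self):
        assert geodesic_distance(0.0, 0.0, 0.0, 180.0) == pytest.approx(
            math.pi * EARTH_RADIUS_M, rel=1e-12
        )

    def test_one_degree_of_latitude(self):
        assert geodesic_distance(54.0, 23.9, 55.0, 23.9) == pytest.approx(
            111_194.93, rel=1e-4
        )


# --------------------------------------------------------------------------
# accelerometer


class TestNormalizeAccel:
    def test_peak_one_axis_unchanged(self):
        df = pd.DataFrame({"t": [0, 1000, 2000], "x": [0.5, -1.0, 0.25], "y": 0.0, "z": 0.0})
        out = normalize_accel(df)
        assert list(out["x"]) == [0.5, -1.0, 0.25]

    def test_direct_formula(self):
        df = pd.DataFrame({"t": [0, 1000], "x": [2.0, -4.0], "y": [1.0, 1.0], "z": [0.0, 0.0]})
        out = normalize_accel(df)
        assert list(out["x"]) == [0.5, -1.0]
        assert list(out["y"]) == [1.0, 1.0]
        assert list(out["z"]) == [0.0, 0.0]  # zero axis left alone

    def test_random_vector_peak_is_exactly_one(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"t": np.arange(100) * 1000, "x": rng.normal(size=100) * 3,
                           "y": rng.normal(size=100), "z": rng.normal(size=100) * 0.1})
        out = normalize_accel(df)
        for axis in ("x", "y", "z"):
            assert out[axis].abs().max() == pytest.approx(1.0)
            assert (out[axis].abs() <= 1.0).all()


class TestMinuteVariances:
    def test_constant_minute_zero(self, day):
        t = day.t_start + np.arange(60) * 1000
        df = pd.DataFrame({"t": t, "x": 0.3, "y": -0.1, "z": 0.9})
        out = minute_variances(df, day)
        assert len(out) == 1 and out.loc[0, "v"] == 0.0

    def test_alternating_unit_variance(self, day):
        t = day.t_start + np.arange(60) * 1000
        x = np.where(np.arange(60) % 2 == 0, 1.0, -1.0)
        df = pd.DataFrame({"t": t, "x": x, "y": 0.0, "z": 0.0})
        out = minute_variances(df, day)
        assert out.loc[0, "v"] == pytest.approx(1.0)  # population var of +/-1

    def test_matches_independent_variance_oracle(self, day):
        rng = np.random.default_rng(2)
        t = day.t_start + np.arange(180) * 1000
        df = pd.DataFrame({"t": t, "x": rng.normal(size=180),
                           "y": rng.normal(size=180), "z": rng.normal(size=180)})
        out = minute_variances(df, day)
        assert len(out) == 3
        for i in range(3):
            sl = df.iloc[i * 60 : (i + 1) * 60]
            expected = sum(
                float(np.mean((sl[a] - sl[a].mean()) ** 2)) for a in ("x", "y", "z")
            )
            assert out.loc[i, "v"] == pytest.approx(expected)

    def test_single_sample_minutes_omitted(self, day):
        df = pd.DataFrame({"t": [day.t_start, day.t_start + 120_000], "x": 1.0, "y": 0.0, "z": 0.0})
        assert len(minute_variances(df, day)) == 0


def test_activity_ratio_thresholding():
    v = pd.DataFrame({"minute_t": np.arange(1440) * 60_000, "v": 0.0})
    assert activity_duration_ratio(v) == 0.0
    v.loc[: 144 - 1, "v"] = 1e-3
    assert activity_duration_ratio(v) == pytest.approx(0.1)
    # boundary: exactly the threshold counts as active (below-threshold is steady)
    boundary = pd.DataFrame({"minute_t": [0, 60_000], "v": [1e-4, 0.99e-4]})
    assert activity_duration_ratio(boundary) == pytest.approx(0.5)
    assert math.isnan(activity_duration_ratio(v.iloc[:0]))


# --------------------------------------------------------------------------
# GPS speeds and movement


def _gps(day, seconds, lats, lons):
    return pd.DataFrame(
        {"t": day.t_start + np.asarray(seconds, dtype=np.int64) * 1000,
         "lat": lats, "lon": lons, "alt": 60.0}
    )


class TestSpeeds:
    def test_stationary_zero(self, day, config):
        df = _gps(day, np.arange(0, 600, 10), 54.9, 23.9)
        speeds = compute_speeds(df, config)
        assert (speeds["speed_kmh"] == 0).all()
        assert movement_duration_ratio(speeds, config) == 0.0

    def test_hundred_meters_in_sixty_seconds_is_six_kmh(self, day, config):
        lat2 = 54.9 + 100.0 / M_PER_DEG
        df = _gps(day, [0, 60], [54.9, lat2], 23.9)
        speeds = compute_speeds(df, config)
        assert len(speeds) == 1
        assert speeds.loc[0, "speed_kmh"] == pytest.approx(6.0, rel=1e-3)

    def test_long_gaps_excluded(self, day, config):
        df = _gps(day, [0, 7200], [54.9, 54.95], 23.9)
        assert len(compute_speeds(df, config)) == 0
        assert math.isnan(movement_duration_ratio(compute_speeds(df, config), config))

    def test_driving_speed_not_movement(self, day, config):
        # 60 km/h due north for 10 minutes
        sec = np.arange(0, 600, 10)
        lat = 54.9 + (60 / 3.6) * sec / M_PER_DEG
        speeds = compute_speeds(_gps(day, sec, lat, 23.9), config)
        assert movement_duration_ratio(speeds, config) == 0.0

    def test_planted_walk_fraction(self, day, config):
        # 1 h walking at 5 km/h within 10 h of observation
        sec = np.arange(0, 36000, 10)
        walking = sec < 3600
        disp = np.cumsum(np.where(walking, (5 / 3.6) * 10.0, 0.0))
        lat = 54.9 + disp / M_PER_DEG
        speeds = compute_speeds(_gps(day, sec, lat, 23.9), config)
        assert movement_duration_ratio(speeds, config) == pytest.approx(0.1, abs=0.002)


# --------------------------------------------------------------------------
# home inference and distances


class TestHome:
    def _night_seconds(self, n):
        # 03:00 local start; fixes every 20 s
        return 3 * 3600 + np.arange(n) * 20

    def test_unanimous_mode(self, day, config):
        df = _gps(day, self._night_seconds(100), 54.9, 23.9)
        home = infer_home(df, config)
        assert home.lat == pytest.approx(54.9) and home.lon == pytest.approx(23.9)
        assert not home.low_confidence

    def test_majority_mode(self, day, config):
        sec = self._night_seconds(100)
        lat = np.where(np.arange(100) < 90, 54.9, 54.95)
        home = infer_home(_gps(day, sec, lat, 23.9), config)
        assert home.lat == pytest.approx(54.9)

    def test_no_night_fixes_falls_back_flagged(self, day, config):
        df = _gps(day, 12 * 3600 + np.arange(50) * 30, 54.91, 23.91)
        home = infer_home(df, config)
        assert home.low_confidence
        assert home.lat == pytest.approx(54.91)

    def test_recovery_under_gps_noise(self, day, config):
        rng = np.random.default_rng(3)
        sec = self._night_seconds(500)
        lat = 54.9 + rng.normal(0, 5.0, 500) / M_PER_DEG
        lon = 23.9 + rng.normal(0, 5.0, 500) / (M_PER_DEG * math.cos(math.radians(54.9)))
        home = infer_home(_gps(day, sec, lat, lon), config)
        assert geodesic_distance(home.lat, home.lon, 54.9, 23.9) < 10.0


class TestHomeRatios:
    home = HomeLocation(54.9, 23.9)

    def test_whole_day_at_home(self, day, config):
        df = _gps(day, np.arange(0, 86400, 60), 54.9, 23.9)
        assert time_at_home_ratio(df, self.home, config) == 1.0
        assert mean_distance_to_home(df, self.home) == 0.0

    def test_day_at_remote_site(self, day, config):
        df = _gps(day, np.arange(0, 86400, 60), 54.9 + 5000 / M_PER_DEG, 23.9)
        assert time_at_home_ratio(df, self.home, config) == 0.0

    def test_half_day_at_ten_km(self, day, config):
        sec = np.arange(0, 86400, 60)
        lat = np.where(sec < 43200, 54.9, 54.9 + 10_000 / M_PER_DEG)
        df = _gps(day, sec, lat, 23.9)
        assert mean_distance_to_home(df, self.home) == pytest.approx(5.0, rel=1e-3)

    def test_one_degree_north_is_111_km(self, day):
        df = _gps(day, [0, 60], 55.9, 23.9)
        assert mean_distance_to_home(df, self.home) == pytest.approx(111.195, rel=1e-4)


# --------------------------------------------------------------------------
# places of interest


def brute_force_place_count(df, radius_m=100.0, gap_s=300.0, min_dwell_s=1800.0):
    """Naive re-implementation of sequential dwell extraction and merging."""
    t = df["t"].to_numpy() / 1000.0
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()
    clusters, cur = [], [0]
    for i in range(1, len(t)):
        clat = float(np.mean(lat[cur]))
        clon = float(np.mean(lon[cur]))
        if t[i] - t[cur[-1]] > gap_s or geodesic_distance(lat[i], lon[i], clat, clon) > radius_m:
            clusters.append(cur)
            cur = [i]
        else:
            cur.append(i)
    clusters.append(cur)
    visits = [
        (float(np.mean(lat[c])), float(np.mean(lon[c])))
        for c in clusters
        if t[c[-1]] - t[c[0]] >= min_dwell_s
    ]
    places: list[tuple[float, float]] = []
    for v in visits:
        if not any(geodesic_distance(v[0], v[1], p[0], p[1]) <= radius_m for p in places):
            places.append(v)
    return len(places)


def _trajectory(day, legs):
    """Build a fix sequence from (duration_s, lat, lon) dwell legs."""
    sec, lats, lons = [], [], []
    t = 0
    for dur, lat, lon in legs:
        ticks = np.arange(0, dur + 1, 60)
        sec.extend(t + ticks)
        lats.extend([lat] * len(ticks))
        lons.extend([lon] * len(ticks))
        t += dur + 120  # displacement break between legs
    return _gps(day, np.array(sec), np.array(lats), np.array(lons))


class TestDetectPoi:
    def test_stationary_day_single_place(self, day, config):
        df = _gps(day, np.arange(0, 86400, 60), 54.9, 23.9)
        assert len(detect_poi(df, config)) == 1

    def test_hand_built_day(self, day, config):
        d = 1000 / M_PER_DEG  # ~1 km spacing between locations
        df = _trajectory(
            day,
            [
                (8 * 3600, 54.9, 23.9),  # home
                (45 * 60, 54.9 + d, 23.9),  # cafe: counts
                (2 * 3600, 54.9 + 2 * d, 23.9),  # clinic: counts
                (29 * 60 - 60, 54.9 + 3 * d, 23.9),  # short stop: below 30 min
            ],
        )
        pois = detect_poi(df, config)
        assert len(pois) == 3
        assert brute_force_place_count(df) == 3

    def test_nearby_dwells_merge_into_one_place(self, day, config):
        """Two separate 40-min visits 50 m apart are one place (100-m rule)."""
        d50 = 50 / M_PER_DEG
        d1km = 1000 / M_PER_DEG
        df = _trajectory(
            day,
            [
                (40 * 60, 54.9, 23.9),
                (10 * 60, 54.9 + d1km, 23.9),  # brief far errand splits clusters
                (40 * 60, 54.9 + d50, 23.9),
            ],
        )
        pois = detect_poi(df, config)
        assert len(pois) == 1
        assert pois[0].n_visits == 2
        assert brute_force_place_count(df) == 1

    def test_matches_brute_force_on_random_trajectories(self, day, config):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(50, 500))
            dt = rng.choice([15, 60, 400], size=n, p=[0.5, 0.4, 0.1])
            sec = np.cumsum(dt)
            # random walk mixing dwells and jumps
            jump = rng.random(n) < 0.1
            step = np.where(jump, rng.normal(0, 300, n), rng.normal(0, 3, n))
            lat = 54.9 + np.cumsum(step) / M_PER_DEG
            lon = 23.9 + np.cumsum(np.where(jump, rng.normal(0, 300, n), 0.0)) / M_PER_DEG
            df = _gps(day, sec, lat, lon)
            assert len(detect_poi(df, config)) == brute_force_place_count(df)


# --------------------------------------------------------------------------
# screen time


class TestScreenTime:
    def _events(self, day, pairs):
        rows = []
        for on_s, off_s in pairs:
            rows.append((day.t_start + on_s * 1000, "screen_on"))
            rows.append((day.t_start + off_s * 1000, "screen_off"))
        df = pd.DataFrame(rows, columns=["t", "state"]).sort_values("t")
        return df.reset_index(drop=True)

    def test_no_events_zero(self, day):
        assert screen_time_ratio(pd.DataFrame({"t": [], "state": []}), day, 1.0) == 0.0

    def test_six_hours_is_quarter_day(self, day):
        events = self._events(day, [(10 * 3600, 16 * 3600)])
        assert screen_time_ratio(events, day, 1.0) == pytest.approx(0.25)

    def test_open_session_truncated_at_day_end(self, day):
        events = pd.DataFrame({"t": [day.t_start + 23 * 3600 * 1000], "state": ["screen_on"]})
        assert screen_time_ratio(events, day, 1.0) == pytest.approx(1 / 24)

    def test_leading_off_assumes_session_from_day_start(self, day):
        events = pd.DataFrame({"t": [day.t_start + 3600 * 1000], "state": ["screen_off"]})
        assert screen_time_ratio(events, day, 1.0) == pytest.approx(1 / 24)

    def test_coverage_scales_denominator(self, day):
        events = self._events(day, [(0, 6 * 3600)])
        assert screen_time_ratio(events, day, 0.5) == pytest.approx(0.5)
        assert math.isnan(screen_time_ratio(events, day, 0.0))

    def test_ratio_clipped_at_one(self, day):
        events = self._events(day, [(0, 20 * 3600)])
        assert screen_time_ratio(events, day, 0.5) == 1.0


# --------------------------------------------------------------------------
# invariances and the two-week rule


def test_translation_invariance_in_longitude(config):
    """A rigid longitude shift leaves every GPS feature unchanged.

    The great-circle metric is exactly invariant under rotations about the
    polar axis, so all count- and distance-based features must agree to
    floating-point precision. (Latitude shifts change the local east-west
    metric by ~tan(lat) * dlat and are only approximately invariant.)
    """
    from phenotrack.synthetic_data import make_cohort_profiles, simulate_subject

    profile = make_cohort_profiles({"no_fear": 1}, seed=9, config=config)[0]
    streams, _ = simulate_subject(profile, 2, config=config)
    shifted = dict(streams)
    shifted["gps"] = streams["gps"].assign(lon=streams["gps"]["lon"] + 0.25)
    base = extract_daily_features(streams, config, "s")
    moved = extract_daily_features(shifted, config, "s")
    for col in ["movement_duration_ratio", "time_home_ratio", "distance_home_km", "n_poi"]:
        np.testing.assert_allclose(
            base[col].to_numpy(), moved[col].to_numpy(), rtol=1e-6, err_msg=col
        )


def test_amplitude_rescaling_invariance(config, day):
    """Doubling raw accelerometer amplitudes does not change activity."""
    rng = np.random.default_rng(10)
    t = day.t_start + np.arange(7200) * 1000
    sd = np.where((np.arange(7200) // 60) % 3 == 0, 0.05, 0.0005)
    df = pd.DataFrame({"t": t, "x": rng.normal(0, 1, 7200) * sd,
                       "y": rng.normal(0, 1, 7200) * sd, "z": 1.0 + rng.normal(0, 1, 7200) * sd})
    ratios = []
    for scale in (1.0, 2.0):
        scaled = df.assign(x=df.x * scale, y=df.y * scale, z=df.z * scale)
        v = minute_variances(normalize_accel(scaled), day)
        ratios.append(activity_duration_ratio(v, config.accel_variance_threshold_g2))
    assert ratios[0] == pytest.approx(ratios[1])


def test_two_week_rule_and_means(config):
    def make_daily(sid, n_valid, n_invalid=0):
        n = n_valid + n_invalid
        return pd.DataFrame(
            {
                "subject_id": sid,
                "date": [Date(2022, 9, 5) + timedelta(days=i) for i in range(n)],
                "coverage_ratio": [1.0] * n_valid + [0.2] * n_invalid,
                "activity_duration_ratio": np.linspace(0.2, 0.8, n),
                "movement_duration_ratio": 0.1,
                "time_home_ratio": 0.7,
                "distance_home_km": 3.0,
                "n_poi": 2.0,
                "screen_time_ratio": 0.2,
                "valid": [True] * n_valid + [False] * n_invalid,
            }
        )

    daily = pd.concat([make_daily("keep", 20), make_daily("drop", 10, 5)], ignore_index=True)
    means = two_week_means(daily, config)
    assert len(means) == 1
    assert list(means["subject_id"]) == ["keep"]
    # mean over the first 14 valid days only
    expected = np.linspace(0.2, 0.8, 20)[:14].mean()
    assert means.loc[0, "activity_duration_ratio"] == pytest.approx(expected)


def test_ratio_features_bounded(recovery_cohort):
    """Every extracted ratio lies in [0, 1]; distances and POI non-negative."""
    for col in ["coverage_ratio_est", "activity_duration_ratio_est",
                "movement_duration_ratio_est", "time_home_ratio_est", "screen_time_ratio_est"]:
        vals = recovery_cohort[col].dropna()
        assert ((vals >= 0) & (vals <= 1)).all(), col
    assert (recovery_cohort["distance_home_km_est"].dropna() >= 0).all()
    assert (recovery_cohort["n_poi_est"].dropna() >= 1).all()
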