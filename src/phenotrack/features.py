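"""Behavioral feature extraction from passive smartphone sensor streams.

Six per-day variables summarise a subject's behavior:

* **activity_duration_ratio** — fraction of accelerometer-observed minutes in
  which the phone's state changed: the summed per-minute variance of the
  (normalized) x, y, z axes is at or above 0.0001 g^2. Minutes below the
  threshold are taken as "phone state did not change".
* **movement_duration_ratio** — fraction of GPS-observed time spent moving at
  walking/jogging speed, i.e. computed speeds in (v_min, 10] km/h.
* **time_home_ratio** — fraction of GPS-observed time spent within the home
  radius; home is the modal night-time (02:00-05:00 local) location.
* **distance_home_km** — mean geodesic distance of the day's fixes to home.
* **n_poi** — number of distinct places of interest visited: locations where
  the subject dwelt at least 30 min, a 100 m radius defining "same place".
* **screen_time_ratio** — fraction of the (coverage-scaled) day with the
  screen on, from power-state events.

Duration features are normalized by the day's data coverage so that
collection outages do not masquerade as behavioral change.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .sensor_io import (
    DayWindow,
    aggregate_by_second,
    collapse_repeated_states,
    daily_coverage,
    day_windows,
)

__all__ = [
    "EARTH_RADIUS_M",
    "HomeLocation",
    "Poi",
    "FEATURE_COLUMNS",
    "geodesic_distance",
    "normalize_accel",
    "minute_variances",
    "activity_duration_ratio",
    "compute_speeds",
    "movement_duration_ratio",
    "infer_home",
    "time_at_home_ratio",
    "mean_distance_to_home",
    "detect_poi",
    "screen_time_ratio",
    "extract_daily_features",
    "two_week_means",
]

logger = logging.getLogger(__name__)

#: WGS84 mean Earth radius (haversine great-circle distance), meters
EARTH_RADIUS_M = 6371.0088e3

#: per-day feature table columns, in output order
FEATURE_COLUMNS = [
    "subject_id",
    "date",
    "coverage_ratio",
    "activity_duration_ratio",
    "movement_duration_ratio",
    "time_home_ratio",
    "distance_home_km",
    "n_poi",
    "screen_time_ratio",
    "valid",
]


@dataclass(frozen=True)
class HomeLocation:
    lat: float
    lon: float
    radius_m: float = 10.0
    low_confidence: bool = False


@dataclass(frozen=True)
class Poi:
    lat: float
    lon: float
    first_entry: int  # ms
    last_exit: int  # ms
    dwell_s: float
    n_visits: int = 1


def geodesic_distance(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in meters between WGS84 coordinates (haversine).

    Symmetric, zero iff the points coincide; accepts scalars or arrays.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(v, dtype=float)) for v in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def normalize_accel(samples: pd.DataFrame) -> pd.DataFrame:
    """Divide each accelerometer axis by its maximum absolute value.

    The maximum is taken over the subject's whole record, so normalization is
    a single global rescaling per axis (values end up in [-1, 1]); this
    removes device-specific amplitude differences. An axis that is
    identically zero is left as zeros.
    """
    if samples.empty:
        raise ValueError("cannot normalize an empty accelerometer record")
    out = samples.copy()
    for axis in ("x", "y", "z"):
        peak = float(out[axis].abs().max())
        if peak > 0:
            out[axis] = out[axis] / peak
    return out


def minute_variances(samples: pd.DataFrame, day: DayWindow) -> pd.DataFrame:
    """Summed per-minute population variance of the three axes.

    ``v_m = var(x_m) + var(y_m) + var(z_m)`` for each clock minute ``m`` of
    the day with at least two (second-aggregated) samples; minutes with fewer
    samples are omitted. Returns columns ``minute_t`` (ms, start of minute)
    and ``v``.
    """
    if samples.empty:
        return pd.DataFrame({"minute_t": pd.Series(dtype=np.int64), "v": pd.Series(dtype=float)})
    t = samples["t"].to_numpy()
    mask = day.contains(t)
    sub = samples.loc[mask]
    if sub.empty:
        return pd.DataFrame({"minute_t": pd.Series(dtype=np.int64), "v": pd.Series(dtype=float)})
    minute = sub["t"].to_numpy() // 60_000
    grouped = sub[["x", "y", "z"]].groupby(minute)
    counts = grouped.size()
    var_sum = grouped.var(ddof=0).sum(axis=1)
    keep = counts >= 2
    return pd.DataFrame(
        {
            "minute_t": (var_sum.index[keep].to_numpy() * 60_000).astype(np.int64),
            "v": var_sum[keep].to_numpy(),
        }
    )


def activity_duration_ratio(
    variances: pd.DataFrame, threshold_g2: float = 1e-4
) -> float:
    """Fraction of observed minutes whose variance reaches the threshold.

    Minutes below the threshold are stationary ("phone state did not
    change"); activity is the complement among observed minutes. ``nan``
    when no minutes were observed.
    """
    if variances.empty:
        return float("nan")
    active = int((variances["v"].to_numpy() >= threshold_g2).sum())
    return active / len(variances)


def compute_speeds(
    samples: pd.DataFrame, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-interval speeds (km/h) from consecutive GPS fixes.

    Fixes are decimated to one per ``speed_baseline_s`` (first fix of each
    bin) before differencing; the baseline suppresses fix-to-fix GPS jitter
    that would otherwise dominate speeds at 1 Hz. Each speed is attributed to
    the interval between the paired fixes; intervals longer than
    ``gps_gap_s`` are excluded (treated as unobserved). Returns columns
    ``t_start`` (ms), ``dt_s``, ``speed_kmh``.
    """
    cfg = config or PipelineConfig()
    empty = pd.DataFrame(
        {"t_start": pd.Series(dtype=np.int64), "dt_s": pd.Series(dtype=float), "speed_kmh": pd.Series(dtype=float)}
    )
    if len(samples) < 2:
        return empty
    t = samples["t"].to_numpy()
    baseline_ms = max(1, int(round(cfg.speed_baseline_s * 1000)))
    bins = (t - t[0]) // baseline_ms
    first_of_bin = np.concatenate([[True], bins[1:] != bins[:-1]])
    sub = samples.loc[first_of_bin]
    if len(sub) < 2:
        return empty
    t = sub["t"].to_numpy()
    lat = sub["lat"].to_numpy()
    lon = sub["lon"].to_numpy()
    dt_s = np.diff(t) / 1000.0
    dist_m = geodesic_distance(lat[:-1], lon[:-1], lat[1:], lon[1:])
    keep = (dt_s > 0) & (dt_s <= cfg.gps_gap_s)
    speed_kmh = np.divide(dist_m / 1000.0, dt_s / 3600.0, out=np.zeros_like(dt_s), where=dt_s > 0)
    return pd.DataFrame(
        {"t_start": t[:-1][keep], "dt_s": dt_s[keep], "speed_kmh": speed_kmh[keep]}
    )


def movement_duration_ratio(
    speeds: pd.DataFrame, config: PipelineConfig | None = None
) -> float:
    """Fraction of GPS-observed time spent at walking/jogging speed.

    Movement is speed in ``(movement_speed_min_kmh, movement_speed_max_kmh]``
    km/h: the upper bound excludes vehicle travel, the lower bound residual
    GPS jitter. The denominator is all observed interval time (gap-excluded
    intervals count for neither). ``nan`` with no observed time.
    """
    cfg = config or PipelineConfig()
    if speeds.empty:
        return float("nan")
    dt = speeds["dt_s"].to_numpy()
    v = speeds["speed_kmh"].to_numpy()
    observed = dt.sum()
    if observed <= 0:
        return float("nan")
    moving = dt[(v > cfg.movement_speed_min_kmh) & (v <= cfg.movement_speed_max_kmh)].sum()
    return float(moving / observed)


def _parse_clock(s: str) -> float:
    hh, mm = s.split(":")
    return int(hh) + int(mm) / 60.0


def _local_hours(t_ms: np.ndarray, tz: str | ZoneInfo) -> np.ndarray:
    zone = str(tz)
    idx = pd.to_datetime(t_ms, unit="ms", utc=True).tz_convert(zone)
    return idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0 + idx.second.to_numpy() / 3600.0


def infer_home(
    samples: pd.DataFrame, config: PipelineConfig | None = None
) -> HomeLocation:
    """Infer the home location from night-time GPS fixes.

    The most frequent coordinates between 02:00 and 05:00 local time over the
    whole record define home: fixes are snapped to a grid of
    ``home_grid_decimals`` decimal degrees (4 decimals is about 11 m,
    matching the 10 m same-place radius), and home is the centroid of the
    fixes in the modal grid cell. With no night fixes at all the mode is
    taken over all fixes instead and the result flagged low-confidence.
    """
    cfg = config or PipelineConfig()
    if samples.empty:
        raise ValueError("cannot infer home from an empty GPS record")
    lo, hi = (_parse_clock(s) for s in cfg.night_window)
    hours = _local_hours(samples["t"].to_numpy(), cfg.timezone)
    night = (hours >= lo) & (hours < hi)
    low_confidence = not bool(night.any())
    sub = samples if low_confidence else samples.loc[night]
    lat = sub["lat"].to_numpy()
    lon = sub["lon"].to_numpy()
    grid_lat = np.round(lat, cfg.home_grid_decimals)
    grid_lon = np.round(lon, cfg.home_grid_decimals)
    cells = pd.DataFrame({"glat": grid_lat, "glon": grid_lon})
    modal = cells.value_counts().index[0]
    member = (grid_lat == modal[0]) & (grid_lon == modal[1])
    return HomeLocation(
        lat=float(lat[member].mean()),
        lon=float(lon[member].mean()),
        radius_m=cfg.home_radius_m,
        low_confidence=low_confidence,
    )


def time_at_home_ratio(
    samples: pd.DataFrame, home: HomeLocation, config: PipelineConfig | None = None
) -> float:
    """Fraction of the day's GPS-observed time spent at home.

    Membership uses the 10 m home radius widened by a GPS-noise allowance
    (default +20 m); each second-aggregated fix stands for one observed
    second. ``nan`` with no fixes.
    """
    cfg = config or PipelineConfig()
    if samples.empty:
        return float("nan")
    d = geodesic_distance(samples["lat"].to_numpy(), samples["lon"].to_numpy(), home.lat, home.lon)
    radius = home.radius_m + cfg.home_noise_allowance_m
    return float(np.mean(d <= radius))


def mean_distance_to_home(samples: pd.DataFrame, home: HomeLocation) -> float:
    """Mean geodesic distance (km) of the day's fixes to home; nan if none."""
    if samples.empty:
        return float("nan")
    d = geodesic_distance(samples["lat"].to_numpy(), samples["lon"].to_numpy(), home.lat, home.lon)
    return float(np.mean(d)) / 1000.0


def detect_poi(
    samples: pd.DataFrame,
    config: PipelineConfig | None = None,
    home: HomeLocation | None = None,
) -> list[Poi]:
    """Detect the day's places of interest by sequential dwell extraction.

    A cluster opens at the first fix and extends while fixes stay within
    ``poi_radius_m`` (100 m) of its running centroid; a fix outside the
    radius, or a time gap longer than ``gps_gap_s``, closes it. Clusters
    dwelling at least ``poi_min_dwell_min`` become visits, and visits whose
    centroids lie within the radius of an earlier visit's centroid merge into
    one place; the home place counts unless ``exclude_home_from_poi``.
    Returns the distinct places; ``len()`` of the result is the day's POI
    count.
    """
    cfg = config or PipelineConfig()
    if samples.empty:
        return []
    t = samples["t"].to_numpy()
    lat = np.radians(samples["lat"].to_numpy())
    lon = np.radians(samples["lon"].to_numpy())
    radius = cfg.poi_radius_m
    gap_ms = cfg.gps_gap_s * 1000.0
    min_dwell_ms = cfg.poi_min_dwell_min * 60_000.0

    visits: list[tuple[float, float, int, int, int]] = []  # (lat_r, lon_r, t0, t1, n)

    def close(sum_lat: float, sum_lon: float, n: int, t0: int, t1: int) -> None:
        if t1 - t0 >= min_dwell_ms:
            visits.append((sum_lat / n, sum_lon / n, t0, t1, n))

    sum_lat = lat[0]
    sum_lon = lon[0]
    n = 1
    t0 = t1 = t[0]
    for i in range(1, len(t)):
        c_lat = sum_lat / n
        c_lon = sum_lon / n
        # haversine to the running centroid, in scalar math for speed
        sdlat = math.sin((lat[i] - c_lat) / 2.0)
        sdlon = math.sin((lon[i] - c_lon) / 2.0)
        a = sdlat * sdlat + math.cos(c_lat) * math.cos(lat[i]) * sdlon * sdlon
        d = 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a)))
        if t[i] - t1 > gap_ms or d > radius:
            close(sum_lat, sum_lon, n, t0, t1)
            sum_lat, sum_lon, n, t0 = lat[i], lon[i], 1, t[i]
        else:
            sum_lat += lat[i]
            sum_lon += lon[i]
            n += 1
        t1 = t[i]
    close(sum_lat, sum_lon, n, t0, t1)

    # merge visits into distinct places: a visit joins the place of the first
    # earlier visit whose centroid lies within the POI radius
    places: list[dict] = []
    for v_lat, v_lon, v_t0, v_t1, _ in visits:
        assigned = None
        for place in places:
            sdlat = math.sin((v_lat - place["lat_r"]) / 2.0)
            sdlon = math.sin((v_lon - place["lon_r"]) / 2.0)
            a = sdlat * sdlat + math.cos(place["lat_r"]) * math.cos(v_lat) * sdlon * sdlon
            if 2.0 * EARTH_RADIUS_M * math.asin(min(1.0, math.sqrt(a))) <= radius:
                assigned = place
                break
        if assigned is None:
            places.append(
                {"lat_r": v_lat, "lon_r": v_lon, "t0": v_t0, "t1": v_t1, "dwell": v_t1 - v_t0, "n_visits": 1}
            )
        else:
            assigned["t1"] = max(assigned["t1"], v_t1)
            assigned["dwell"] += v_t1 - v_t0
            assigned["n_visits"] += 1

    result = [
        Poi(
            lat=math.degrees(p["lat_r"]),
            lon=math.degrees(p["lon_r"]),
            first_entry=int(p["t0"]),
            last_exit=int(p["t1"]),
            dwell_s=p["dwell"] / 1000.0,
            n_visits=p["n_visits"],
        )
        for p in places
    ]
    if cfg.exclude_home_from_poi and home is not None:
        cutoff = home.radius_m + cfg.home_noise_allowance_m + cfg.poi_radius_m
        result = [
            p for p in result if geodesic_distance(p.lat, p.lon, home.lat, home.lon) > cutoff
        ]
    return result


def _screen_sessions(events: pd.DataFrame) -> list[tuple[float, float]]:
    """Pair collapsed power events into (start_ms, end_ms) sessions.

    A leading ``screen_off`` opens a session at -inf (the day-window
    intersection truncates it to the day start); a trailing ``screen_on``
    leaves a session open to +inf (truncated at the day end).
    """
    sessions: list[tuple[float, float]] = []
    start: float | None = None
    for t, state in zip(events["t"].to_numpy(), events["state"]):
        if state == "screen_on":
            start = float(t)
        else:
            sessions.append((start if start is not None else -math.inf, float(t)))
            start = None
    if start is not None:
        sessions.append((start, math.inf))
    return sessions


def screen_time_ratio(
    events: pd.DataFrame, day: DayWindow, coverage: float
) -> float:
    """Fraction of the coverage-scaled day with the screen on.

    Session durations (screen_on to the next screen_off) are intersected
    with the day window and divided by the day length scaled by coverage;
    the result is clipped to [0, 1]. ``nan`` when coverage is zero.
    """
    if coverage <= 0 or not np.isfinite(coverage):
        return float("nan")
    if events.empty:
        return 0.0
    events = collapse_repeated_states(events.sort_values("t", kind="stable"))
    total_ms = 0.0
    for start, end in _screen_sessions(events):
        lo = max(start, day.t_start)
        hi = min(end, day.t_end)
        if hi > lo:
            total_ms += hi - lo
    ratio = (total_ms / 1000.0) / (day.duration_s * coverage)
    return float(min(1.0, ratio))


def extract_daily_features(
    streams: dict[str, pd.DataFrame],
    config: PipelineConfig | None = None,
    subject_id: str = "",
) -> pd.DataFrame:
    """Extract the six per-day features for one subject.

    ``streams`` maps stream kinds (``accel``, ``gps``, ``power``, ``log``) to
    raw sample DataFrames; any kind may be absent, in which case its features
    are ``nan`` (and, with no log stream, coverage bookkeeping is unavailable
    and assumed complete). Returns one row per local calendar day spanning
    the record, with ``valid`` marking days whose coverage reaches the
    configured floor. The inferred home is stored in ``df.attrs["home"]``.
    """
    cfg = config or PipelineConfig()
    accel = streams.get("accel")
    gps = streams.get("gps")
    power = streams.get("power")
    logs = streams.get("log")

    t_values = [s["t"] for s in streams.values() if s is not None and len(s)]
    if not t_values:
        return pd.DataFrame(columns=FEATURE_COLUMNS)
    t_min = int(min(s.min() for s in t_values))
    t_max = int(max(s.max() for s in t_values))

    accel_sec = None
    if accel is not None and len(accel):
        accel_sec = aggregate_by_second(accel)
        if not cfg.threshold_on_raw:
            accel_sec = normalize_accel(accel_sec)
    gps_sec = None
    home = None
    if gps is not None and len(gps):
        gps_sec = aggregate_by_second(gps)
        home = infer_home(gps_sec, cfg)
    if power is not None and len(power):
        power = collapse_repeated_states(power.sort_values("t", kind="stable"))

    rows = []
    for day in day_windows(subject_id, t_min, t_max, cfg.timezone):
        if logs is not None and len(logs):
            cov = daily_coverage(logs, day, cfg.expected_files_per_day)
        else:
            cov = 1.0
        row: dict = {
            "subject_id": subject_id,
            "date": day.date,
            "coverage_ratio": cov,
            "activity_duration_ratio": float("nan"),
            "movement_duration_ratio": float("nan"),
            "time_home_ratio": float("nan"),
            "distance_home_km": float("nan"),
            "n_poi": float("nan"),
            "screen_time_ratio": float("nan"),
        }
        if accel_sec is not None:
            variances = minute_variances(accel_sec, day)
            row["activity_duration_ratio"] = activity_duration_ratio(
                variances, cfg.accel_variance_threshold_g2
            )
        if gps_sec is not None:
            in_day = gps_sec.loc[day.contains(gps_sec["t"].to_numpy())]
            if len(in_day):
                row["movement_duration_ratio"] = movement_duration_ratio(
                    compute_speeds(in_day, cfg), cfg
                )
                row["time_home_ratio"] = time_at_home_ratio(in_day, home, cfg)
                row["distance_home_km"] = mean_distance_to_home(in_day, home)
                row["n_poi"] = float(len(detect_poi(in_day, cfg, home)))
        if power is not None and len(power):
            row["screen_time_ratio"] = screen_time_ratio(power, day, cov)
        row["valid"] = bool(cov >= cfg.coverage_floor)
        rows.append(row)

    out = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    out.attrs["home"] = home
    return out


_NUMERIC_FEATURES = [
    "activity_duration_ratio",
    "movement_duration_ratio",
    "time_home_ratio",
    "distance_home_km",
    "n_poi",
    "screen_time_ratio",
]


def two_week_means(
    daily: pd.DataFrame, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-subject means over the first two weeks of valid days.

    Subjects are eligible for cohort analysis only with at least
    ``min_valid_days`` (14) valid days; ineligible subjects are excluded
    with a logged reason. Means are taken over each subject's first 14 valid
    days ("a mean of 2 weeks"). One row per eligible subject.
    """
    cfg = config or PipelineConfig()
    rows = []
    for subject_id, sub in daily.groupby("subject_id", sort=True):
        valid = sub.loc[sub["valid"].astype(bool)].sort_values("date")
        if len(valid) < cfg.min_valid_days:
            logger.info(
                "subject %s excluded: %d valid day(s) < %d required",
                subject_id,
                len(valid),
                cfg.min_valid_days,
            )
            continue
        window = valid.head(cfg.min_valid_days)
        row = {"subject_id": subject_id, "n_valid_days": len(valid)}
        for col in _NUMERIC_FEATURES:
            row[col] = float(window[col].mean())
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "n_valid_days", *_NUMERIC_FEATURES])
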