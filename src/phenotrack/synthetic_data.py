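"""Synthetic oncology-cohort generator with exact per-day ground truth.

Each subject gets a behavioral profile (home location, a catalog of places of
interest, daily fractions of time at home / walking / on the screen, an
activity level and a coverage model) drawn around group-level means, and each
simulated day is built as a physical itinerary: overnight and evening blocks
at home, drives to places of interest with dwells of at least 40 minutes,
walking bouts out-and-back from home, hourly screen sessions, and hourly
"Create new data files" log records thinned by per-hour dropout. Raw streams
are then emitted exactly as a collection app would record them — duty-cycled
1 Hz GPS with temporally correlated position error, duty-cycled 10 Hz
accelerometer, power events, log records — together with the day's ground
truth for all six behavioral features.

Group effects are injected at the behavioral-parameter level, never by
perturbing extracted features, so the full extraction stack is exercised.
Ground truth is computed from the noise-free emitted trajectory and the
post-dropout observation pattern: it is what an error-free extractor would
observe, so recovery tests measure extraction error rather than sampling
error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import PipelineConfig, SimulateConfig
from .sensor_io import CREATE_FILES_MESSAGE, local_day_window, write_stream
from .features import FEATURE_COLUMNS

__all__ = [
    "SubjectProfile",
    "FEAR_EFFECTS",
    "VACCINATION_EFFECTS",
    "DEFAULT_EFFECTS",
    "POI_WEEKLY_PATTERN",
    "QUANTITY_BOUNDS",
    "null_effects",
    "make_cohort_profiles",
    "make_trend_profiles",
    "simulate_day",
    "simulate_subject",
    "simulate_cohort",
    "simulate_daily_features",
    "make_cohort_table",
]

#: meters per degree of latitude on the mean-radius sphere
M_PER_DEG_LAT = 6371.0088e3 * math.pi / 180.0

_HOME, _VISIT, _WALK, _DRIVE = 0, 1, 2, 3

QUANTITIES = (
    "activity_duration_ratio",
    "movement_duration_ratio",
    "time_home_ratio",
    "distance_home_km",
    "n_poi",
    "screen_time_ratio",
)

#: feasible ranges for behavioral parameters, (lo, hi)
QUANTITY_BOUNDS: dict[str, tuple[float, float]] = {
    "activity_duration_ratio": (0.05, 0.95),
    "movement_duration_ratio": (0.005, 0.30),
    "time_home_ratio": (0.05, 0.88),
    "distance_home_km": (0.5, 60.0),
    "n_poi": (1.0, 7.0),
    "screen_time_ratio": (0.02, 0.80),
}

# Group-level behavioral targets: published two-week cohort means for each
# comparison group; parameter-level SDs are half the published cohort SDs
# (which mix between- and within-subject variance), capped at 0.75 * mean for
# the heavy-tailed distance summaries.
FEAR_EFFECTS: dict[str, dict[str, tuple[float, float]]] = {
    "fear": {
        "movement_duration_ratio": (0.105, 0.0265),
        "distance_home_km": (8.3, 6.2),
        "time_home_ratio": (0.744, 0.113),
        "n_poi": (2.711, 0.611),
        "activity_duration_ratio": (0.552, 0.073),
        "screen_time_ratio": (0.222, 0.0755),
    },
    "no_fear": {
        "movement_duration_ratio": (0.071, 0.0235),
        "distance_home_km": (15.7, 11.8),
        "time_home_ratio": (0.633, 0.127),
        "n_poi": (3.461, 0.8065),
        "activity_duration_ratio": (0.538, 0.091),
        "screen_time_ratio": (0.187, 0.087),
    },
}

VACCINATION_EFFECTS: dict[str, dict[str, tuple[float, float]]] = {
    "fully": {
        "n_poi": (2.908, 0.4925),
        "distance_home_km": (43.498, 32.6),
        "time_home_ratio": (0.688, 0.1275),
        "activity_duration_ratio": (0.561, 0.072),
        "movement_duration_ratio": (0.101, 0.0245),
        "screen_time_ratio": (0.159, 0.0565),
    },
    "partially": {
        "n_poi": (3.837, 0.4915),
        "distance_home_km": (7.588, 5.69),
        "time_home_ratio": (0.654, 0.1005),
        "activity_duration_ratio": (0.548, 0.0765),
        "movement_duration_ratio": (0.092, 0.021),
        "screen_time_ratio": (0.156, 0.049),
    },
    "unvaccinated": {
        "n_poi": (2.704, 0.368),
        "distance_home_km": (7.829, 4.86),
        "time_home_ratio": (0.723, 0.044),
        "activity_duration_ratio": (0.608, 0.054),
        "movement_duration_ratio": (0.062, 0.0205),
        "screen_time_ratio": (0.151, 0.029),
    },
}

DEFAULT_EFFECTS: dict[str, dict[str, tuple[float, float]]] = {
    **FEAR_EFFECTS,
    **VACCINATION_EFFECTS,
}

# Week-indexed mean POI counts by vaccination group over the 14-week study:
# the partially vaccinated start near 3.3 and ramp to about 4 after the first
# week; the fully vaccinated stay below 3 with a dip in week 11 and maximum
# in week 14; the unvaccinated peak at 2.5 at enrollment and bottom out at
# 2.0 in week 11.
POI_WEEKLY_PATTERN: dict[str, list[float]] = {
    "partially": [3.3, 3.6, 3.8, 3.85, 3.85, 3.9, 3.9, 3.9, 3.9, 3.9, 3.9, 3.95, 3.95, 4.0],
    "fully": [2.8, 2.8, 2.75, 2.75, 2.7, 2.7, 2.7, 2.65, 2.65, 2.6, 2.6, 2.7, 2.85, 3.0],
    "unvaccinated": [2.5, 2.45, 2.4, 2.35, 2.3, 2.25, 2.2, 2.15, 2.1, 2.05, 2.0, 2.05, 2.1, 2.15],
}


def null_effects(labels: Sequence[str]) -> dict[str, dict[str, tuple[float, float]]]:
    """Identical behavioral targets for every label (exchangeable groups)."""
    base = FEAR_EFFECTS["no_fear"]
    return {label: dict(base) for label in labels}


@dataclass
class SubjectProfile:
    """Behavioral ground-truth parameters of one synthetic subject."""

    subject_id: str
    home_lat: float
    home_lon: float
    #: planar offsets (m east, m north) and distances (km) of the place
    #: catalog; index 0 is the anchor place (clinic/workplace)
    place_xy: np.ndarray = field(repr=False, default=None)
    place_dist_km: np.ndarray = field(repr=False, default=None)
    time_home_frac: float = 0.68
    n_poi_rate: float = 3.0
    walk_frac: float = 0.09
    activity_frac: float = 0.55
    screen_frac: float = 0.18
    distance_target_km: float = 10.0
    walk_speed_kmh: float = 5.0
    drive_speed_kmh: float = 60.0
    min_visit_dwell_s: float = 2400.0
    p_drop_hour: float = 0.05
    fear_flag: Optional[bool] = None
    vaccination_status: Optional[str] = None
    group_label: str = ""
    #: optional week-indexed POI-rate schedule overriding ``n_poi_rate``
    n_poi_weekly: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.time_home_frac <= 1.0:
            raise ValueError("time_home_frac must lie in [0, 1]")
        if self.time_home_frac + self.walk_frac > 1.0:
            raise ValueError("home and walking fractions exceed the day")
        if self.walk_speed_kmh <= 0 or self.drive_speed_kmh <= 0:
            raise ValueError("speeds must be positive")


def _truncated_normal(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    """Normal draw truncated symmetrically about the mean (mean-preserving)."""
    half = min(3.0 * sd, mean - lo, hi - mean)
    if half <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(200):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= half:
            return float(x)
    return float(mean)


def _solve_anchor_distance(
    away_s: float,
    walk_s: float,
    k_typical: int,
    target_km: float,
    drive_kmh: float,
    min_dwell_s: float,
) -> float:
    """Anchor-place distance whose typical day realizes the distance target.

    Mean distance to home integrates dwell time at distance d plus the
    drive itself (average distance d/2 over 2*d/v hours); solved by a damped
    fixed point, clipped to [0.5, 80] km. Published cohort means driven by
    outliers saturate the cap; the realized group mean then falls below the
    target, which the generator accepts (a physical day is the constraint).
    """
    minors = max(0, k_typical - 1)
    contrib_minor = minors * 3000.0 * 1.5  # km*s from nearby places
    # round-trip drive time may not crowd out walking bouts or dwells
    d_hi = float(np.clip(0.15 * max(0.0, away_s - walk_s) * drive_kmh / 3600.0, 2.0, 80.0))
    d = float(np.clip(target_km * 3.0, 0.5, d_hi))
    for _ in range(8):
        travel_s = 2.0 * d / drive_kmh * 3600.0
        dwell = max(min_dwell_s, away_s - walk_s - travel_s - minors * 3000.0)
        contrib_travel = 3600.0 * d * d / drive_kmh
        d_new = (target_km * 86400.0 - contrib_minor - contrib_travel) / dwell
        d = float(np.clip(0.5 * (d + d_new), 0.5, d_hi))
    return d


def make_cohort_profiles(
    n_per_group: Mapping[str, int],
    effect_config: Mapping[str, Mapping[str, tuple[float, float]]] | None = None,
    seed: int = 0,
    config: PipelineConfig | None = None,
) -> list[SubjectProfile]:
    """Draw subject profiles for each group around its behavioral targets.

    ``n_per_group`` maps group labels to subject counts; ``effect_config``
    maps labels to ``{quantity: (mean, sd)}`` and defaults to the published
    group summaries (fear / no_fear, fully / partially / unvaccinated).
    Parameters are truncated-normal around the group means. A mean outside
    its feasible range is a validation error.
    """
    cfg = config or PipelineConfig()
    sim = cfg.simulate
    effects = dict(effect_config) if effect_config is not None else DEFAULT_EFFECTS
    rng = np.random.default_rng(seed)
    profiles: list[SubjectProfile] = []
    sid = 0
    for label, n in n_per_group.items():
        if label not in effects:
            raise ValueError(f"no effect configuration for group {label!r}")
        spec = effects[label]
        for q, (mean, _sd) in spec.items():
            lo, hi = QUANTITY_BOUNDS[q]
            if not lo <= mean <= hi:
                raise ValueError(f"{label}.{q}: mean {mean} outside [{lo}, {hi}]")
        for _ in range(n):
            draws = {
                q: _truncated_normal(rng, mean, sd, *QUANTITY_BOUNDS[q])
                for q, (mean, sd) in spec.items()
            }
            # a subject cannot walk more than the time left outside home
            draws["movement_duration_ratio"] = min(
                draws["movement_duration_ratio"],
                0.85 * (1.0 - draws["time_home_ratio"]),
            )
            home_lat = sim.home_lat + rng.uniform(-0.05, 0.05)
            home_lon = sim.home_lon + rng.uniform(-0.08, 0.08)
            # 5 nearby minor places at spread bearings, >= 0.4 km from home
            bearings = np.radians(rng.permutation(5) * 72.0 + rng.uniform(0, 72))
            dists = rng.uniform(0.4, 2.5, size=5)
            minor_xy = np.column_stack(
                [dists * 1000.0 * np.sin(bearings), dists * 1000.0 * np.cos(bearings)]
            )
            away_s = (1.0 - draws["time_home_ratio"]) * 86400.0
            walk_s = draws["movement_duration_ratio"] * 86400.0
            k_typ = max(1, int(round(draws["n_poi"] - 1.0)))
            d_anchor = _solve_anchor_distance(
                away_s,
                walk_s,
                k_typ,
                draws["distance_home_km"],
                sim.drive_speed_kmh,
                sim.min_visit_dwell_s,
            )
            theta = rng.uniform(0, 2 * math.pi)
            anchor_xy = np.array([d_anchor * 1000.0 * math.sin(theta), d_anchor * 1000.0 * math.cos(theta)])
            profiles.append(
                SubjectProfile(
                    subject_id=f"S{sid:03d}",
                    home_lat=home_lat,
                    home_lon=home_lon,
                    place_xy=np.vstack([anchor_xy, minor_xy]),
                    place_dist_km=np.concatenate([[d_anchor], dists]),
                    time_home_frac=draws["time_home_ratio"],
                    n_poi_rate=draws["n_poi"],
                    walk_frac=draws["movement_duration_ratio"],
                    activity_frac=draws["activity_duration_ratio"],
                    screen_frac=draws["screen_time_ratio"],
                    distance_target_km=draws["distance_home_km"],
                    walk_speed_kmh=sim.walk_speed_kmh,
                    drive_speed_kmh=sim.drive_speed_kmh,
                    min_visit_dwell_s=sim.min_visit_dwell_s,
                    p_drop_hour=sim.p_drop_hour,
                    fear_flag=(label == "fear") if label in FEAR_EFFECTS else None,
                    vaccination_status=label if label in VACCINATION_EFFECTS else None,
                    group_label=label,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
            sid += 1
    return profiles


def make_trend_profiles(
    n_per_group: Mapping[str, int] | None = None,
    seed: int = 0,
    config: PipelineConfig | None = None,
    subject_sd: float = 0.35,
) -> list[SubjectProfile]:
    """Vaccination-group profiles with the week-indexed POI schedule.

    Each subject follows the group's weekly POI pattern shifted by a
    subject-level offset; other behavioral parameters come from the
    vaccination-group targets.
    """
    if n_per_group is None:
        n_per_group = {"fully": 40, "partially": 15, "unvaccinated": 15}
    unknown = set(n_per_group) - set(POI_WEEKLY_PATTERN)
    if unknown:
        raise ValueError(f"no weekly POI pattern for groups: {sorted(unknown)}")
    profiles = make_cohort_profiles(n_per_group, VACCINATION_EFFECTS, seed=seed, config=config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    for p in profiles:
        offset = rng.normal(0.0, subject_sd)
        p.n_poi_weekly = np.asarray(POI_WEEKLY_PATTERN[p.group_label]) + offset
    return profiles


# ---------------------------------------------------------------------------
# itinerary construction


@dataclass
class _Segment:
    t0: float
    t1: float
    kind: int
    ax: float
    ay: float
    bx: float
    by: float
    place: int  # catalog index for visits, -1 otherwise


def _build_itinerary(
    profile: SubjectProfile,
    day_len_s: float,
    k_away: int,
    rng,
    away_target_s: float | None = None,
) -> list[_Segment]:
    """Plan one day as home blocks, drives + dwells, and walking bouts.

    The subject sleeps at home (which keeps the 02:00-05:00 night window
    there), spends daytime on up to ``k_away`` place visits (anchor first)
    and walking bouts, and returns home each time. Visits get priority over
    walking when the away-time budget is tight; each dwell is at least the
    profile's minimum so that every planted visit is a detectable place of
    interest.
    """
    D = day_len_s
    w0, w1 = 28800.0, D - 7200.0
    budget = w1 - w0
    v = profile.drive_speed_kmh
    min_dwell = profile.min_visit_dwell_s
    away_target = (
        away_target_s if away_target_s is not None else (1.0 - profile.time_home_frac) * D
    )
    away_target = min(away_target, 0.9 * budget)
    walk_target = profile.walk_frac * D

    ids: list[int] = []
    if k_away >= 1:
        ids.append(0)
        if k_away >= 2:
            minors = 1 + rng.permutation(len(profile.place_dist_km) - 1)[: k_away - 1]
            ids.extend(int(i) for i in minors)

    def travel_time(sel: list[int]) -> float:
        return sum(2.0 * profile.place_dist_km[i] / v * 3600.0 for i in sel)

    while ids and travel_time(ids) + min_dwell * len(ids) > 0.95 * away_target:
        # drop the most travel-expensive place first: preserves the day's
        # POI count (nearby places are cheap) at the cost of distance
        ids.remove(max(ids, key=lambda i: profile.place_dist_km[i]))
    # likewise drop a nearby visit rather than squeeze walking bouts hard
    while (
        len(ids) > 1
        and min(walk_target, away_target - travel_time(ids) - min_dwell * len(ids))
        < 0.8 * walk_target
    ):
        ids.pop()
    travel = travel_time(ids)
    walk_s = min(walk_target, max(0.0, away_target - travel - min_dwell * len(ids)))
    visits_total = max(0.0, away_target - travel - walk_s) if ids else 0.0
    if not ids:
        walk_s = min(walk_target, away_target)

    dwells: dict[int, float] = {}
    if ids:
        minor_dwells = [min_dwell * rng.uniform(1.0, 1.4) for _ in ids[1:]]
        anchor_dwell = visits_total - sum(minor_dwells)
        if anchor_dwell < min_dwell:
            avail = visits_total - min_dwell
            scale = avail / sum(minor_dwells) if minor_dwells else 0.0
            minor_dwells = [max(min_dwell, m * scale) for m in minor_dwells]
            anchor_dwell = min_dwell
        dwells[ids[0]] = anchor_dwell
        for i, dw in zip(ids[1:], minor_dwells):
            dwells[i] = dw

    total_act = walk_s + travel + sum(dwells.values())
    if total_act > 0.92 * budget:  # cannot happen for realistic fractions, but stay safe
        avail = 0.92 * budget - travel
        scale = max(0.0, avail) / max(1.0, walk_s + sum(dwells.values()))
        walk_s *= scale
        dwells = {i: max(min_dwell, dw * scale) for i, dw in dwells.items()}
        total_act = walk_s + travel + sum(dwells.values())

    units: list[tuple[str, int, float]] = [("visit", i, dwells[i]) for i in ids]
    if walk_s >= 1200.0:
        units.append(("walk", -1, walk_s / 2.0))
        units.append(("walk", -1, walk_s / 2.0))
    elif walk_s >= 300.0:
        units.append(("walk", -1, walk_s))
    rng.shuffle(units)

    slack = budget - total_act
    gaps = rng.dirichlet(np.ones(len(units) + 1)) * slack if units else np.array([slack])

    segs: list[_Segment] = []

    def add(t0: float, t1: float, kind: int, a, b, place: int = -1) -> None:
        if t1 - t0 < 1e-9:
            return
        if kind == _HOME and segs and segs[-1].kind == _HOME:
            segs[-1].t1 = t1
            return
        segs.append(_Segment(t0, t1, kind, a[0], a[1], b[0], b[1], place))

    home = (0.0, 0.0)
    add(0.0, w0, _HOME, home, home)
    t = w0
    for gap, unit in zip(gaps, [*units, None]):
        add(t, t + gap, _HOME, home, home)
        t += gap
        if unit is None:
            break
        kind, place, dur = unit
        if kind == "visit":
            pos = tuple(profile.place_xy[place])
            tt = profile.place_dist_km[place] / v * 3600.0
            add(t, t + tt, _DRIVE, home, pos)
            add(t + tt, t + tt + dur, _VISIT, pos, pos, place)
            add(t + tt + dur, t + 2 * tt + dur, _DRIVE, pos, home)
            t += 2 * tt + dur
        else:
            theta = rng.uniform(0, 2 * math.pi)
            reach = profile.walk_speed_kmh / 3.6 * dur / 2.0
            far = (reach * math.sin(theta), reach * math.cos(theta))
            add(t, t + dur / 2.0, _WALK, home, far)
            add(t + dur / 2.0, t + dur, _WALK, far, home)
            t += dur
    add(t, D, _HOME, home, home)
    return segs


# ---------------------------------------------------------------------------
# emission


def _first_fix_second(u: int, cycle: int, on: int) -> int:
    c = u % cycle
    return u if c < on else u + cycle - c


def _last_fix_second(w: int, cycle: int, on: int) -> int:
    c = w % cycle
    return w if c < on else w - c + on - 1


def _kept_intervals(a: float, b: float, kept: np.ndarray) -> list[tuple[float, float]]:
    """Maximal sub-intervals of [a, b) lying inside kept hours."""
    chunks: list[tuple[float, float]] = []
    cur: tuple[float, float] | None = None
    for h in range(int(a // 3600), int(math.ceil(b / 3600.0))):
        if 0 <= h < len(kept) and kept[h]:
            u, w = max(a, h * 3600.0), min(b, (h + 1) * 3600.0)
            if cur is not None and abs(cur[1] - u) < 1e-6:
                cur = (cur[0], w)
            else:
                if cur is not None:
                    chunks.append(cur)
                cur = (u, w)
        elif cur is not None:
            chunks.append(cur)
            cur = None
    if cur is not None:
        chunks.append(cur)
    return chunks


def _observable_poi_count(
    segs: list[_Segment],
    kept: np.ndarray,
    sim: SimulateConfig,
    min_dwell_s: float = 1800.0,
    include_home: bool = True,
) -> int:
    """Places whose observed fix span reaches the POI dwell threshold.

    A place counts when at least one of its dwell segments has a kept
    contiguous chunk whose first-to-last GPS fix span (on the burst grid)
    reaches ``min_dwell_s`` — exactly what sequential dwell extraction can
    observe on the emitted data.
    """
    cycle, on = sim.gps_cycle_s, sim.gps_burst_on_s
    by_place: dict[int, list[tuple[float, float]]] = {}
    for seg in segs:
        if seg.kind == _HOME and include_home:
            by_place.setdefault(-1, []).append((seg.t0, seg.t1))
        elif seg.kind == _VISIT:
            by_place.setdefault(seg.place, []).append((seg.t0, seg.t1))
    count = 0
    for intervals in by_place.values():
        qualifies = False
        for a, b in intervals:
            for u, w in _kept_intervals(a, b, kept):
                first = _first_fix_second(int(math.ceil(u)), cycle, on)
                last = _last_fix_second(int(math.floor(w - 1e-6)), cycle, on)
                if last >= first and last - first >= min_dwell_s:
                    qualifies = True
                    break
            if qualifies:
                break
        count += int(qualifies)
    return count


def _ar1_noise(rng, n: int, sigma: float, tau: float) -> np.ndarray:
    """Stationary AR(1) series at 1 Hz (correlated GNSS position error)."""
    a = math.exp(-1.0 / tau)
    innov = rng.normal(0.0, sigma * math.sqrt(1.0 - a * a), size=n)
    innov[0] = rng.normal(0.0, sigma)
    return lfilter([1.0], [1.0, -a], innov)


def simulate_day(
    profile: SubjectProfile,
    date: Date,
    rng,
    config: PipelineConfig | None = None,
    day_index: int | None = None,
    emit_streams: bool = True,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Simulate one subject-day; returns raw streams and the day's truth.

    Streams use the on-disk schema of :mod:`phenotrack.sensor_io` with UTC
    millisecond timestamps; the truth dict holds the six behavioral features
    as observable on the emitted (noise-free, post-dropout) data, plus the
    day's coverage. ``emit_streams=False`` skips sensor-noise generation and
    stream assembly (empty frames returned) for large-cohort checks of the
    ground-truth distribution itself; the realization then differs from an
    emitting run because fewer random draws are consumed.
    """
    cfg = config or PipelineConfig()
    sim = cfg.simulate
    day = local_day_window(profile.subject_id, date, cfg.timezone)
    D = int(day.duration_s)
    n_hours = int(math.ceil(D / 3600.0))
    kept = rng.random(n_hours) >= profile.p_drop_hour

    rate = profile.n_poi_rate
    if profile.n_poi_weekly is not None and day_index is not None:
        rate = float(profile.n_poi_weekly[min(day_index // 7, len(profile.n_poi_weekly) - 1)])
    # hourly dropout clips ~1.4 * p_drop of minimum-dwell visits below the
    # 30-min observable threshold; inflate the draw so the expected number
    # of *observable* places still matches the rate
    q_visit = min(0.5, 1.4 * profile.p_drop_hour)
    k_away = int(
        np.clip(round(rng.normal((rate - 1.0) / (1.0 - q_visit), 0.6)), 0, len(profile.place_dist_km))
    )

    # On stay-home days (k_away = 0) away time is walking only, which leaves
    # more home time than the profile fraction; inflate the away target of
    # visit days so the expected home fraction still matches the profile.
    away_base = (1.0 - profile.time_home_frac) * D
    away_target = away_base
    if k_away >= 1:
        p0 = 0.5 * (1.0 + math.erf((0.5 - (rate - 1.0)) / (0.6 * math.sqrt(2.0))))
        p0 = min(p0, 0.5)
        walk_only = min(profile.walk_frac * D, away_base)
        away_target = (away_base - p0 * walk_only) / (1.0 - p0)

    segs = _build_itinerary(profile, float(D), k_away, rng, away_target_s=away_target)
    t0s = np.array([s.t0 for s in segs])
    t1s = np.array([s.t1 for s in segs])
    kinds = np.array([s.kind for s in segs])
    ax = np.array([s.ax for s in segs])
    ay = np.array([s.ay for s in segs])
    bx = np.array([s.bx for s in segs])
    by = np.array([s.by for s in segs])

    coverage = min(1.0, float(kept.sum()) / cfg.expected_files_per_day)
    truth: dict = {
        "subject_id": profile.subject_id,
        "date": date,
        "coverage_ratio": coverage,
        "activity_duration_ratio": float("nan"),
        "movement_duration_ratio": float("nan"),
        "time_home_ratio": float("nan"),
        "distance_home_km": float("nan"),
        "n_poi": float("nan"),
        "screen_time_ratio": float("nan"),
        "valid": bool(coverage >= cfg.coverage_floor),
    }

    # --- GPS ---------------------------------------------------------------
    sec = np.arange(D)
    hour_of = np.minimum(sec // 3600, n_hours - 1)
    fix_s = sec[((sec % sim.gps_cycle_s) < sim.gps_burst_on_s) & kept[hour_of]]
    if len(fix_s):
        idx = np.searchsorted(t0s, fix_s + 0.5, side="right") - 1
        dur = t1s[idx] - t0s[idx]
        frac = np.where(dur > 0, (fix_s - t0s[idx]) / dur, 0.0)
        x = ax[idx] + (bx[idx] - ax[idx]) * frac
        y = ay[idx] + (by[idx] - ay[idx]) * frac
        kind_at_fix = kinds[idx]
        if emit_streams:
            nx = _ar1_noise(rng, D, sim.gps_noise_sigma_m, sim.gps_noise_tau_s)[fix_s]
            ny = _ar1_noise(rng, D, sim.gps_noise_sigma_m, sim.gps_noise_tau_s)[fix_s]
            lat = profile.home_lat + (y + ny) / M_PER_DEG_LAT
            lon = profile.home_lon + (x + nx) / (
                M_PER_DEG_LAT * math.cos(math.radians(profile.home_lat))
            )
            gps = pd.DataFrame(
                {
                    "t": day.t_start + fix_s.astype(np.int64) * 1000,
                    "lat": lat,
                    "lon": lon,
                    "alt": 60.0 + rng.normal(0.0, 3.0, size=len(fix_s)),
                }
            )
        else:
            gps = pd.DataFrame({"t": pd.Series(dtype=np.int64), "lat": [], "lon": [], "alt": []})
        truth["time_home_ratio"] = float(np.mean(kind_at_fix == _HOME))
        truth["movement_duration_ratio"] = float(np.mean(kind_at_fix == _WALK))
        truth["distance_home_km"] = float(np.mean(np.hypot(x, y))) / 1000.0
        truth["n_poi"] = float(
            _observable_poi_count(
                segs,
                kept,
                sim,
                min_dwell_s=cfg.poi_min_dwell_min * 60.0,
                include_home=not cfg.exclude_home_from_poi,
            )
        )
    else:
        gps = pd.DataFrame({"t": pd.Series(dtype=np.int64), "lat": [], "lon": [], "alt": []})

    # --- accelerometer -----------------------------------------------------
    minutes = np.arange(D // 60)
    on_min = ((minutes * 60) % sim.accel_cycle_s) < sim.accel_on_s
    obs_min = minutes[on_min & kept[np.minimum(minutes // 60, n_hours - 1)]]
    accel = pd.DataFrame({"t": pd.Series(dtype=np.int64), "x": [], "y": [], "z": []})
    if len(obs_min):
        active = rng.random(len(obs_min)) < profile.activity_frac
        truth["activity_duration_ratio"] = float(active.mean())
        if emit_streams:
            spm = sim.accel_rate_hz * 60
            step_ms = 1000 // sim.accel_rate_hz
            t_acc = (
                day.t_start
                + obs_min.astype(np.int64)[:, None] * 60_000
                + (np.arange(spm, dtype=np.int64) * step_ms)[None, :]
            ).ravel()
            sd = np.where(active, 0.15, 0.002)[:, None]
            acc_x = (rng.standard_normal((len(obs_min), spm)) * sd).ravel()
            acc_y = (rng.standard_normal((len(obs_min), spm)) * sd).ravel()
            acc_z = 1.0 + (rng.standard_normal((len(obs_min), spm)) * sd).ravel()
            accel = pd.DataFrame({"t": t_acc, "x": acc_x, "y": acc_y, "z": acc_z})

    # --- screen sessions (within hour boundaries) --------------------------
    ev_t: list[int] = []
    ev_state: list[str] = []
    screen_on_total = 0.0
    for h in range(n_hours):
        if not kept[h]:
            continue
        hour_len = min(3600.0, D - h * 3600.0)
        target = float(
            np.clip(profile.screen_frac * hour_len * rng.uniform(0.75, 1.25), 60.0, hour_len - 120.0)
        )
        start = h * 3600.0 + rng.uniform(5.0, hour_len - target - 5.0)
        ev_t.extend([int((day.t_start + start * 1000.0)), int(day.t_start + (start + target) * 1000.0)])
        ev_state.extend(["screen_on", "screen_off"])
        screen_on_total += target
    power = pd.DataFrame({"t": pd.Series(ev_t, dtype=np.int64), "state": ev_state})
    if coverage > 0:
        truth["screen_time_ratio"] = min(1.0, screen_on_total / (D * coverage))

    # --- log records --------------------------------------------------------
    log_t = [day.t_start + h * 3_600_000 for h in range(n_hours) if kept[h]]
    log = pd.DataFrame(
        {"t": pd.Series(log_t, dtype=np.int64), "message": CREATE_FILES_MESSAGE}
    )

    streams = {"accel": accel, "gps": gps, "power": power, "log": log}
    return streams, truth


def simulate_subject(
    profile: SubjectProfile,
    n_days: int,
    start_date: Date = Date(2022, 9, 5),
    config: PipelineConfig | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate a multi-day record; streams concatenated across days."""
    children = np.random.SeedSequence(profile.seed).spawn(n_days)
    parts: dict[str, list[pd.DataFrame]] = {k: [] for k in ("accel", "gps", "power", "log")}
    truths = []
    for i in range(n_days):
        streams, truth = simulate_day(
            profile,
            start_date + timedelta(days=i),
            np.random.default_rng(children[i]),
            config,
            day_index=i,
        )
        for k, df in streams.items():
            if len(df):
                parts[k].append(df)
        truths.append(truth)
    combined = {
        k: (pd.concat(v, ignore_index=True) if v else pd.DataFrame())
        for k, v in parts.items()
    }
    truth_df = pd.DataFrame(truths, columns=FEATURE_COLUMNS)
    return combined, truth_df


def simulate_cohort(
    profiles: Sequence[SubjectProfile],
    weeks: int,
    out_dir: str | Path,
    start_date: Date = Date(2022, 9, 5),
    config: PipelineConfig | None = None,
    overwrite: bool = False,
) -> pd.DataFrame:
    """Write a full cohort dataset in the sensor_io directory layout.

    Emits ``<out_dir>/<subject>/{accel,gps,power,log}.csv`` per subject,
    plus ``ground_truth.csv`` (per-day truth) and ``cohort.csv`` (metadata
    with questionnaire items and dose dates). Deterministic for fixed
    profiles. Returns the ground-truth table.
    """
    if weeks < 2:
        raise ValueError("need at least 2 weeks of simulated data")
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} exists and is not empty (use overwrite)")
    out.mkdir(parents=True, exist_ok=True)
    truths = []
    for profile in profiles:
        streams, truth_df = simulate_subject(profile, 7 * weeks, start_date, config)
        for kind, df in streams.items():
            if len(df):
                write_stream(df, out / profile.subject_id / f"{kind}.csv", kind)
        truths.append(truth_df)
    truth = pd.concat(truths, ignore_index=True)
    truth.to_csv(out / "ground_truth.csv", index=False)
    make_cohort_table(profiles, assessment_date=start_date).to_csv(
        out / "cohort.csv", index=False
    )
    return truth


def simulate_daily_features(
    profiles: Sequence[SubjectProfile],
    weeks: int,
    seed: int = 0,
    start_date: Date = Date(2022, 9, 5),
) -> pd.DataFrame:
    """Fast behavior-level generator: daily feature values without streams.

    Samples each subject's daily feature realizations directly around the
    profile parameters (weekly POI schedules honored), in the per-day
    feature-table schema. Useful for statistics and trend analyses where
    emitting raw sensor streams would add nothing but runtime.
    """
    rows = []
    for i, p in enumerate(profiles):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        for d in range(7 * weeks):
            rate = p.n_poi_rate
            if p.n_poi_weekly is not None:
                rate = float(p.n_poi_weekly[min(d // 7, len(p.n_poi_weekly) - 1)])
            n_poi = 1 + max(0, int(round(rng.normal(rate - 1.0, 0.8))))
            rows.append(
                {
                    "subject_id": p.subject_id,
                    "date": start_date + timedelta(days=d),
                    "coverage_ratio": 1.0,
                    "activity_duration_ratio": float(np.clip(rng.normal(p.activity_frac, 0.04), 0, 1)),
                    "movement_duration_ratio": float(np.clip(rng.normal(p.walk_frac, 0.02), 0, 1)),
                    "time_home_ratio": float(np.clip(rng.normal(p.time_home_frac, 0.04), 0, 1)),
                    "distance_home_km": float(p.distance_target_km * rng.lognormal(0.0, 0.35)),
                    "n_poi": float(n_poi),
                    "screen_time_ratio": float(np.clip(rng.normal(p.screen_frac, 0.03), 0, 1)),
                    "valid": True,
                }
            )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def _items_for_score(raw_sum: int, rng) -> list[int]:
    """Ten 1..5 items summing to ``raw_sum`` (uniformly incremented)."""
    items = [1] * 10
    for _ in range(raw_sum - 10):
        open_idx = [i for i, v in enumerate(items) if v < 5]
        items[open_idx[int(rng.integers(len(open_idx)))]] += 1
    return items


def make_cohort_table(
    profiles: Sequence[SubjectProfile],
    seed: int = 12345,
    assessment_date: Date = Date(2022, 9, 5),
) -> pd.DataFrame:
    """Cohort metadata consistent with each profile's group labels.

    Questionnaire items are drawn to land on the fear side of the >= 50
    dichotomy for fear-labeled subjects (and below for the rest); dose dates
    are placed to reproduce each subject's vaccination status at the
    assessment date.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for p in profiles:
        fear = p.fear_flag if p.fear_flag is not None else bool(rng.random() < 0.25)
        status = (
            p.vaccination_status
            if p.vaccination_status is not None
            else rng.choice(["fully", "partially", "unvaccinated"], p=[0.71, 0.13, 0.16])
        )
        raw = int(rng.integers(30, 47)) if fear else int(rng.integers(10, 30))
        items = _items_for_score(raw, rng)
        if status == "fully":
            dose1 = assessment_date - timedelta(days=int(rng.integers(180, 400)))
            dose2 = dose1 + timedelta(days=int(rng.integers(21, 42)))
        elif status == "partially":
            dose1 = assessment_date - timedelta(days=int(rng.integers(20, 60)))
            dose2 = None
        else:
            dose1 = dose2 = None
        row = {
            "subject_id": p.subject_id,
            "age_group": rng.choice(["18-25", "26-40", "41-64", ">=65"], p=[0.03, 0.12, 0.55, 0.30]),
            "sex": rng.choice(["female", "male"], p=[0.69, 0.31]),
        }
        row.update({f"item{i+1}": items[i] for i in range(10)})
        row["dose1_date"] = dose1.isoformat() if dose1 else ""
        row["dose2_date"] = dose2.isoformat() if dose2 else ""
        row["assessment_date"] = assessment_date.isoformat()
        rows.append(row)
    return pd.DataFrame(rows)
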