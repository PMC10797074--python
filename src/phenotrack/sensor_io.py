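"""Reading, writing and pre-aggregating raw smartphone sensor streams.

Four stream kinds are supported, one CSV file per subject and kind under
``<root>/<subject_id>/<kind>.csv``:

========  =======================================================  ==========
kind      CSV header                                               columns
========  =======================================================  ==========
accel     ``timestamp_ms,x_g,y_g,z_g``                             t, x, y, z
gps       ``timestamp_ms,latitude_deg,longitude_deg,altitude_m``   t, lat, lon, alt
power     ``timestamp_ms,event``                                   t, state
log       ``timestamp_ms,message``                                 t, message
========  =======================================================  ==========

Timestamps are integer milliseconds since the Unix epoch, UTC. Day windows
are defined by local midnight in a configured timezone (daylight-saving days
keep their true 23/25-hour length), because the night-window home-inference
rule and "per day" feature ratios are local-clock semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import date as Date, datetime, time, timedelta
from pathlib import Path
from typing import Iterator
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

__all__ = [
    "STREAM_KINDS",
    "StreamFormatError",
    "DayWindow",
    "read_stream",
    "write_stream",
    "read_subject",
    "iter_subjects",
    "aggregate_by_second",
    "collapse_repeated_states",
    "daily_coverage",
    "day_windows",
    "local_day_window",
]

logger = logging.getLogger(__name__)

#: marker written by the collection app each time it opens a new data file
CREATE_FILES_MESSAGE = "Create new data files"

# kind -> (csv columns, internal columns)
_SCHEMAS: dict[str, tuple[list[str], list[str]]] = {
    "accel": (["timestamp_ms", "x_g", "y_g", "z_g"], ["t", "x", "y", "z"]),
    "gps": (
        ["timestamp_ms", "latitude_deg", "longitude_deg", "altitude_m"],
        ["t", "lat", "lon", "alt"],
    ),
    "power": (["timestamp_ms", "event"], ["t", "state"]),
    "log": (["timestamp_ms", "message"], ["t", "message"]),
}
STREAM_KINDS = tuple(_SCHEMAS)

_POWER_STATES = frozenset({"screen_on", "screen_off"})


class StreamFormatError(ValueError):
    """A stream file does not have the documented header for its kind."""


def read_stream(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one raw stream CSV, returning samples sorted by timestamp.

    Rows with an unparseable timestamp (or, for numeric kinds, unparseable
    values) are skipped with a warning; the count of skipped rows is stored
    in ``df.attrs["n_skipped"]``. A missing or renamed header column raises
    :class:`StreamFormatError` naming the column.
    """
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown stream kind: {kind!r}")
    csv_cols, cols = _SCHEMAS[kind]
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in csv_cols:
        if col not in raw.columns:
            raise StreamFormatError(
                f"{path}: missing column {col!r} required for {kind} streams"
            )
    raw = raw[csv_cols]
    raw.columns = cols
    n = len(raw)
    t = pd.to_numeric(raw["t"], errors="coerce")
    ok = t.notna()
    if kind == "accel":
        for c in ("x", "y", "z"):
            raw[c] = pd.to_numeric(raw[c], errors="coerce")
            ok &= np.isfinite(raw[c])
    elif kind == "gps":
        for c in ("lat", "lon", "alt"):
            raw[c] = pd.to_numeric(raw[c], errors="coerce")
            ok &= np.isfinite(raw[c])
        ok &= raw["lat"].between(-90, 90) & raw["lon"].between(-180, 180)
    elif kind == "power":
        ok &= raw["state"].isin(_POWER_STATES)
    df = raw.loc[ok].copy()
    df["t"] = t[ok].astype(np.int64)
    df = df.sort_values("t", kind="stable").reset_index(drop=True)
    n_skipped = int(n - ok.sum())
    if n_skipped:
        logger.warning("%s: skipped %d malformed row(s)", path, n_skipped)
    df.attrs["n_skipped"] = n_skipped
    return df


def write_stream(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a stream DataFrame back to its CSV dialect (round-trip safe)."""
    if kind not in _SCHEMAS:
        raise ValueError(f"unknown stream kind: {kind!r}")
    csv_cols, cols = _SCHEMAS[kind]
    out = df[cols].copy()
    out.columns = csv_cols
    out["timestamp_ms"] = out["timestamp_ms"].astype(np.int64)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # full repr precision: the round trip must be lossless
    out.to_csv(path, index=False)


def read_subject(root: str | Path, subject_id: str) -> dict[str, pd.DataFrame]:
    """Read all present streams for one subject from the directory layout."""
    streams: dict[str, pd.DataFrame] = {}
    subject_dir = Path(root) / subject_id
    for kind in STREAM_KINDS:
        path = subject_dir / f"{kind}.csv"
        if path.exists():
            streams[kind] = read_stream(path, kind)
    return streams


def iter_subjects(root: str | Path) -> Iterator[str]:
    """Yield subject ids (subdirectory names with at least one stream file)."""
    rootp = Path(root)
    for child in sorted(rootp.iterdir()):
        if child.is_dir() and any((child / f"{k}.csv").exists() for k in STREAM_KINDS):
            yield child.name


def aggregate_by_second(df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate numeric samples to one per epoch second (arithmetic mean).

    Output timestamps are the start of the second (ms). Idempotent: output
    timestamps are already second-aligned, so a second pass is the identity.
    """
    if df.empty:
        return df.copy()
    num_cols = [c for c in df.columns if c != "t"]
    sec = df["t"].to_numpy() // 1000
    grouped = df[num_cols].groupby(sec).mean()
    out = grouped.reset_index(names="t")
    out["t"] = out["t"].astype(np.int64) * 1000
    return out[["t", *num_cols]]


def collapse_repeated_states(events: pd.DataFrame) -> pd.DataFrame:
    """Drop consecutive repeats of the same power state, keeping the first.

    Duplicated OS events (two ``screen_on`` in a row) are common and would
    double-count screen time.
    """
    if events.empty:
        return events.copy()
    keep = events["state"].ne(events["state"].shift())
    return events.loc[keep].reset_index(drop=True)


@dataclass(frozen=True)
class DayWindow:
    """One local calendar day of one subject, as an epoch-ms interval."""

    subject_id: str
    date: Date
    t_start: int  # ms, inclusive
    t_end: int  # ms, exclusive

    @property
    def duration_s(self) -> float:
        return (self.t_end - self.t_start) / 1000.0

    def contains(self, t: np.ndarray | int) -> np.ndarray | bool:
        return (t >= self.t_start) & (t < self.t_end)


def local_day_window(subject_id: str, date: Date, tz: str | ZoneInfo) -> DayWindow:
    """Build the day window bounded by local midnights (DST-aware)."""
    zone = ZoneInfo(tz) if isinstance(tz, str) else tz
    start = datetime.combine(date, time.min, tzinfo=zone)
    end = datetime.combine(date + timedelta(days=1), time.min, tzinfo=zone)
    return DayWindow(subject_id, date, int(start.timestamp() * 1000), int(end.timestamp() * 1000))


def day_windows(
    subject_id: str, t_min: int, t_max: int, tz: str | ZoneInfo
) -> list[DayWindow]:
    """All local day windows covering the span ``[t_min, t_max]`` (ms)."""
    zone = ZoneInfo(tz) if isinstance(tz, str) else tz
    first = datetime.fromtimestamp(t_min / 1000.0, tz=zone).date()
    last = datetime.fromtimestamp(t_max / 1000.0, tz=zone).date()
    out = []
    d = first
    while d <= last:
        out.append(local_day_window(subject_id, d, zone))
        d += timedelta(days=1)
    return out


def daily_coverage(
    logs: pd.DataFrame, day: DayWindow, expected_files_per_day: int = 24
) -> float:
    """Fraction of the day covered by data collection, from log records.

    The app logs one "Create new data files" record per collection file
    (hourly by default); the count within the day, divided by the expected
    count and clamped to 1, scales the denominators of duration features so
    that transmission outages do not deflate them.
    """
    if expected_files_per_day <= 0:
        raise ValueError("expected_files_per_day must be positive")
    if logs.empty:
        return 0.0
    mask = logs["message"].eq(CREATE_FILES_MESSAGE) & day.contains(
        logs["t"].to_numpy()
    )
    return min(1.0, float(mask.sum()) / expected_files_per_day)
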