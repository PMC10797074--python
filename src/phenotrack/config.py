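"""Pipeline configuration.

All thresholds of the feature-extraction stack live in :class:`PipelineConfig`
so that a single object (or YAML file) pins an analysis run. Defaults encode
the published extraction rules: a 0.0001 g^2 per-minute accelerometer-variance
threshold separating stationary from active minutes, a 10 km/h speed ceiling
defining movement (walking/jogging), a 10 m same-place radius for the home
location inferred from the 02:00-05:00 night window, a 100 m radius and 30 min
minimum dwell for places of interest, and a two-week minimum of valid days for
cohort inclusion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["PipelineConfig", "SimulateConfig", "load_config"]


@dataclass
class SimulateConfig:
    """Knobs of the synthetic cohort generator (``simulate.*`` namespace).

    Sampling-rate and duty-cycle defaults emulate a Beiwe-style collection
    app; the coverage model drops whole hours of all sensor data to mimic
    transmission failures (app deleted, battery optimisation, phone off).
    """

    gps_noise_sigma_m: float = 5.0
    #: correlation time of the GPS error process (multipath/atmospheric bias)
    gps_noise_tau_s: float = 1800.0
    gps_burst_on_s: int = 60
    gps_cycle_s: int = 180
    accel_rate_hz: int = 10
    accel_on_s: int = 60
    accel_cycle_s: int = 660
    #: per-hour probability that the app collects nothing that hour
    p_drop_hour: float = 0.05
    walk_speed_kmh: float = 5.0
    drive_speed_kmh: float = 60.0
    #: minimum planted visit dwell, safely above the 30-min detection floor
    min_visit_dwell_s: float = 2400.0
    home_lat: float = 54.8985
    home_lon: float = 23.9036


@dataclass
class PipelineConfig:
    # accelerometer
    accel_variance_threshold_g2: float = 1e-4
    #: apply the variance threshold to raw (un-normalized) axes instead
    threshold_on_raw: bool = False
    # GPS / movement
    movement_speed_max_kmh: float = 10.0
    movement_speed_min_kmh: float = 0.5
    speed_baseline_s: float = 10.0
    gps_gap_s: float = 300.0
    # home / POI
    home_radius_m: float = 10.0
    home_noise_allowance_m: float = 20.0
    poi_radius_m: float = 100.0
    poi_min_dwell_min: float = 30.0
    exclude_home_from_poi: bool = False
    night_window: tuple[str, str] = ("02:00", "05:00")
    home_grid_decimals: int = 4
    # coverage / inclusion
    expected_files_per_day: int = 24
    coverage_floor: float = 0.5
    min_valid_days: int = 14
    timezone: str = "Europe/Vilnius"
    # trends
    loess_span: float = 0.75
    loess_degree: int = 2
    trend_weeks: int = 14
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs: dict[str, Any] = {}
        sim_kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key == "simulate" and isinstance(value, Mapping):
                sim_kwargs.update(value)
            elif key.startswith("simulate."):
                sim_kwargs[key.split(".", 1)[1]] = value
            elif key in known:
                kwargs[key] = value
            else:
                raise KeyError(f"unknown config key: {key!r}")
        if "night_window" in kwargs:
            kwargs["night_window"] = tuple(kwargs["night_window"])
        cfg = cls(**kwargs)
        sim_known = {f.name for f in dataclasses.fields(SimulateConfig)}
        for key in sim_kwargs:
            if key not in sim_known:
                raise KeyError(f"unknown config key: simulate.{key!r}")
        cfg.simulate = SimulateConfig(**sim_kwargs)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["night_window"] = list(self.night_window)
        return d


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; ``None`` returns the defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_mapping(data)
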