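"""Shared fixtures: configs, day windows and the simulated recovery cohort."""

from __future__ import annotations

from datetime import date as Date

import pandas as pd
import pytest

from phenotrack.config import PipelineConfig
from phenotrack.features import extract_daily_features
from phenotrack.sensor_io import local_day_window
from phenotrack.synthetic_data import make_cohort_profiles, simulate_subject


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def day(config):
    """A plain 24-hour local day window."""
    return local_day_window("S000", Date(2022, 9, 6), config.timezone)


@pytest.fixture(scope="session")
def recovery_cohort() -> pd.DataFrame:
    """Extraction vs ground truth for 20 simulated subjects x 14 days.

    One row per subject-day with ``*_est`` (extracted) and ``*_true``
    (planted, observable) columns for all six features. Session-scoped:
    simulating and extracting the full cohort dominates suite runtime.
    """
    cfg = PipelineConfig()
    profiles = make_cohort_profiles({"fear": 10, "no_fear": 10}, seed=1, config=cfg)
    frames = []
    for profile in profiles:
        streams, truth = simulate_subject(profile, 14)
        daily = extract_daily_features(streams, cfg, profile.subject_id)
        frames.append(
            daily.merge(truth, on=["subject_id", "date"], suffixes=("_est", "_true"))
        )
    return pd.concat(frames, ignore_index=True)
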