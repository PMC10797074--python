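"""COVID-19 fear scoring and vaccination-status classification.

The COVID-19 Fears Questionnaire for Chronic Medical Conditions has 10 items
rated 1 (not at all) to 5 (extremely). The raw sum (10-50) is linearly
rescaled to 0-100; a score >= 50 defines the "fear" group.

Vaccination status is one of three categories derived from dose dates at the
assessment date: *fully* (at least 2 weeks after the second dose), *partially*
(more than 2 weeks after the first dose, including two-dose recipients not yet
fully protected), or *unvaccinated* (no doses).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as Date
from typing import Optional, Sequence

import pandas as pd

__all__ = [
    "N_ITEMS",
    "FearResponse",
    "VaccinationRecord",
    "score_fear",
    "classify_vaccination",
    "score_cohort",
]

N_ITEMS = 10
_MIN_RAW = N_ITEMS * 1
_MAX_RAW = N_ITEMS * 5
FULL_PROTECTION_DAYS = 14


@dataclass(frozen=True)
class FearResponse:
    items: tuple[int, ...]
    raw_sum: int
    score_0_100: float
    fear_flag: bool


@dataclass(frozen=True)
class VaccinationRecord:
    dose1_date: Optional[Date]
    dose2_date: Optional[Date]
    assessment_date: Date
    status: str
    recent_dose: bool = False


def score_fear(items: Sequence[int]) -> FearResponse:
    """Score the 10-item questionnaire.

    The 0-100 score is ``(raw_sum - 10) * 100 / 40``; it is affine and
    order-preserving, mapping raw sums 10..50 onto 0, 2.5, ..., 100.
    Missing or out-of-range items are an error (the analysis uses complete
    responses only), reported with the offending item index.
    """
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} items, got {len(items)}")
    clean: list[int] = []
    for i, item in enumerate(items, start=1):
        if item is None or (isinstance(item, float) and pd.isna(item)):
            raise ValueError(f"item {i} is missing")
        val = int(item)
        if val != item or not 1 <= val <= 5:
            raise ValueError(f"item {i} out of range 1..5: {item!r}")
        clean.append(val)
    raw = sum(clean)
    score = (raw - _MIN_RAW) * 100.0 / (_MAX_RAW - _MIN_RAW)
    return FearResponse(tuple(clean), raw, score, score >= 50.0)


def classify_vaccination(
    dose1_date: Optional[Date],
    dose2_date: Optional[Date],
    assessment_date: Date,
) -> VaccinationRecord:
    """Classify vaccination status at the assessment date.

    Boundary semantics: exactly 14 days since dose 2 counts as fully
    ("at least 2 weeks"), while exactly 14 days since dose 1 is not yet
    partially ("more than 2 weeks"). A recipient whose doses are all too
    recent is classified partially with ``recent_dose=True`` rather than
    silently binned.
    """
    if dose1_date is None and dose2_date is not None:
        raise ValueError("dose2_date present without dose1_date")
    if dose1_date is not None and dose2_date is not None and dose2_date < dose1_date:
        raise ValueError("dose2_date before dose1_date")
    for label, d in (("dose1_date", dose1_date), ("dose2_date", dose2_date)):
        if d is not None and d > assessment_date:
            raise ValueError(f"{label} after assessment_date")

    if dose1_date is None:
        status, recent = "unvaccinated", False
    elif (
        dose2_date is not None
        and (assessment_date - dose2_date).days >= FULL_PROTECTION_DAYS
    ):
        status, recent = "fully", False
    elif (assessment_date - dose1_date).days > FULL_PROTECTION_DAYS:
        status, recent = "partially", False
    else:
        status, recent = "partially", True
    return VaccinationRecord(dose1_date, dose2_date, assessment_date, status, recent)


def _parse_date(value) -> Optional[Date]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, Date):
        return value
    s = str(value).strip()
    if not s:
        return None
    return Date.fromisoformat(s)


def score_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Score a cohort metadata table.

    Expects columns ``subject_id, item1..item10, dose1_date, dose2_date,
    assessment_date`` (ISO dates, empty = absent); demographic columns are
    passed through. Adds ``fear_raw_sum, fear_score, fear_flag,
    vaccination_status, recent_dose``.
    """
    item_cols = [f"item{i}" for i in range(1, N_ITEMS + 1)]
    missing = [c for c in [*item_cols, "assessment_date"] if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    out = cohort.copy()
    scored = [score_fear([row[c] for c in item_cols]) for _, row in cohort.iterrows()]
    out["fear_raw_sum"] = [s.raw_sum for s in scored]
    out["fear_score"] = [s.score_0_100 for s in scored]
    out["fear_flag"] = [s.fear_flag for s in scored]
    records = [
        classify_vaccination(
            _parse_date(row.get("dose1_date")),
            _parse_date(row.get("dose2_date")),
            _parse_date(row["assessment_date"]),
        )
        for _, row in cohort.iterrows()
    ]
    out["vaccination_status"] = [r.status for r in records]
    out["recent_dose"] = [r.recent_dose for r in records]
    return out
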