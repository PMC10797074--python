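"""Local polynomial regression (LOESS) trends of daily features over study time.

At each evaluation point a low-degree polynomial is fitted by weighted least
squares over the span-nearest neighbors with tricube weights; the fit is a
linear smoother, so a pointwise standard error follows from the smoother row
norm and a globally estimated residual scale. Pointwise 95% bands are
``fitted +/- 1.96 * se``. Group trends are evaluated on a common weekly grid
(weeks 1-14 by default); group separation is read off where bands do not
overlap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = ["TrendFit", "loess_fit", "group_trends", "bands_overlap", "weekly_grid"]

logger = logging.getLogger(__name__)

#: normal 97.5% quantile for the pointwise 95% band
CI_MULTIPLIER = 1.96


@dataclass
class TrendFit:
    group: str
    grid: np.ndarray
    fitted: np.ndarray
    se: np.ndarray
    flags: list[str] = field(default_factory=list)
    #: residuals at the data points (same order as the cleaned input)
    residuals: np.ndarray | None = None

    @property
    def ci_low(self) -> np.ndarray:
        return self.fitted - CI_MULTIPLIER * self.se

    @property
    def ci_high(self) -> np.ndarray:
        return self.fitted + CI_MULTIPLIER * self.se

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "week": self.grid / 7.0 + 0.5,
                "study_day": self.grid,
                "fitted": self.fitted,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )


def _smoother_row(
    x: np.ndarray, x0: float, k: int, degree: int
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Weight vector l(x0) with l(x0)@y the local fit; returns (idx, l, widened)."""
    d = np.abs(x - x0)
    order = np.argsort(d, kind="stable")
    widened = False
    idx = order[:k]
    # guard: a window of coincident x values cannot support the polynomial
    while len(np.unique(x[idx])) < degree + 1 and k < len(x):
        k += 1
        idx = order[:k]
        widened = True
    h = d[idx].max()
    if h <= 0:
        w = np.ones(len(idx))
    else:
        w = (1.0 - np.minimum(d[idx] / h, 1.0) ** 3) ** 3
        w = np.maximum(w, 1e-9)  # keep boundary points from degenerating
    xs = x[idx] - x0
    design = np.vander(xs, degree + 1, increasing=True)
    wd = design * w[:, None]
    gram = design.T @ wd
    first_row = np.linalg.solve(gram, wd.T)[0]
    return idx, first_row, widened


def loess_fit(
    x,
    y,
    span: float = 0.75,
    degree: int = 2,
    grid=None,
    group: str = "",
) -> TrendFit:
    """LOESS fit of ``y`` over ``x`` with pointwise standard errors.

    ``span`` is the fraction of points in each local window (tricube
    weighted); ``degree`` is 1 (local linear) or 2 (local quadratic). By
    construction the fit reproduces any polynomial of the given degree
    exactly. ``grid`` defaults to the sorted unique x values. Windows with
    fewer distinct x than ``degree + 1`` are widened locally and flagged.

    The residual scale is estimated globally from the fit at the data
    points, ``sigma^2 = RSS / (n - tr(L))``, and ``se(x0) = sigma *
    ||l(x0)||`` from the linear-smoother form ``fit(x0) = l(x0) @ y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 points for a LOESS fit")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    k = max(degree + 2, int(np.ceil(span * n)))
    k = min(k, n)

    flags: list[str] = []
    # residual scale from the fit at the data points; for large n the scale
    # is estimated on an even-spaced (deterministic) subsample of the
    # x-ordered data, which leaves sigma^2 unbiased at a fraction of the cost
    if n > 3000:
        eval_idx = np.argsort(x, kind="stable")[:: int(np.ceil(n / 1500))]
    else:
        eval_idx = np.arange(n)
    fitted_data = np.full(n, np.nan)
    trace = 0.0
    for i in eval_idx:
        idx, l_row, widened = _smoother_row(x, x[i], k, degree)
        fitted_data[i] = l_row @ y[idx]
        pos = np.nonzero(idx == i)[0]
        if len(pos):
            trace += l_row[pos[0]]
        if widened and "window_widened" not in flags:
            flags.append("window_widened")
    n_eval = len(eval_idx)
    resid_eval = y[eval_idx] - fitted_data[eval_idx]
    rss = float((resid_eval**2).sum())
    dof = max(n_eval - trace, 1.0)
    sigma2 = rss / dof

    if grid is None:
        grid = np.unique(x)
    grid = np.asarray(grid, dtype=float)
    fitted = np.empty(len(grid))
    se = np.empty(len(grid))
    for j, x0 in enumerate(grid):
        idx, l_row, widened = _smoother_row(x, x0, k, degree)
        fitted[j] = l_row @ y[idx]
        se[j] = np.sqrt(sigma2 * float(l_row @ l_row))
        if widened and "window_widened" not in flags:
            flags.append("window_widened")
    return TrendFit(
        group=group, grid=grid, fitted=fitted, se=se, flags=flags,
        residuals=y - fitted_data,
    )


def weekly_grid(weeks: int = 14) -> np.ndarray:
    """Weekly midpoints in study days: 3.5, 10.5, ... for weeks 1..n."""
    return 3.5 + 7.0 * np.arange(weeks)


def group_trends(
    daily: pd.DataFrame,
    grouping: dict[str, str] | pd.Series,
    feature: str,
    config: PipelineConfig | None = None,
) -> dict[str, TrendFit]:
    """Per-group LOESS trends of one daily feature over study time.

    Study time is days since each subject's first valid day; all groups are
    evaluated on a common weekly-midpoint grid spanning ``trend_weeks``
    weeks. Groups with fewer than 5 subjects are fitted but flagged
    ``low_n``.
    """
    cfg = config or PipelineConfig()
    if isinstance(grouping, pd.Series):
        grouping = grouping.to_dict()
    valid = daily.loc[daily["valid"].astype(bool)].copy()
    valid = valid.dropna(subset=[feature])
    first_day = valid.groupby("subject_id")["date"].transform("min")
    valid["study_day"] = [
        (d - f).days for d, f in zip(valid["date"], first_day)
    ]
    valid["group"] = valid["subject_id"].map(grouping)
    valid = valid.dropna(subset=["group"])
    grid = weekly_grid(cfg.trend_weeks)

    fits: dict[str, TrendFit] = {}
    for label, sub in valid.groupby("group", sort=True):
        fit = loess_fit(
            sub["study_day"].to_numpy(),
            sub[feature].to_numpy(),
            span=cfg.loess_span,
            degree=cfg.loess_degree,
            grid=grid,
            group=str(label),
        )
        fit.se = fit.se * math.sqrt(
            _design_effect(fit.residuals, sub["subject_id"].to_numpy())
        )
        if sub["subject_id"].nunique() < 5:
            fit.flags.append("low_n")
            logger.warning("group %r has < 5 subjects; trend flagged low_n", label)
        fits[str(label)] = fit
    return fits


def _design_effect(residuals: np.ndarray, subjects: np.ndarray) -> float:
    """Variance inflation for repeated measures within subjects.

    Daily observations are clustered within subjects; iid pointwise bands
    would shrink with total subject-days and understate uncertainty about
    the cohort-level curve. The classic design effect ``1 + (m - 1) * ICC``
    (m = mean observations per subject, ICC = between-subject share of the
    residual variance, estimated by one-way moments) rescales the band so
    that it reflects the effective number of subjects.
    """
    df = pd.DataFrame({"e": residuals, "s": subjects})
    groups = df.groupby("s")["e"]
    m = float(groups.size().mean())
    if m <= 1 or len(groups) < 2:
        return 1.0
    within = float(groups.var(ddof=1).mean())
    between_raw = float(groups.mean().var(ddof=1))
    sigma_b2 = max(0.0, between_raw - within / m)
    total = sigma_b2 + within
    if total <= 0:
        return 1.0
    icc = sigma_b2 / total
    return 1.0 + (m - 1.0) * icc


def bands_overlap(a: TrendFit, b: TrendFit) -> np.ndarray:
    """Boolean per grid point: do the two 95% bands overlap there?"""
    if not np.array_equal(a.grid, b.grid):
        raise ValueError("trend fits must share a grid")
    return (a.ci_low <= b.ci_high) & (b.ci_low <= a.ci_high)
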