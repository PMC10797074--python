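"""Nonparametric cohort statistics implemented from their defining formulas.

Pearson chi-squared on contingency tables (no continuity correction), the
Mann-Whitney U test (rank formulation, tie-corrected normal approximation,
exact permutation enumeration for small samples), and the Kruskal-Wallis H
test (tie-corrected). Only tail probabilities come from scipy's distribution
functions; the statistics themselves are computed here so their conventions
(plain Pearson, U = min(U_a, U_b)) are explicit and testable.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm as norm_dist
from scipy.stats import rankdata

__all__ = [
    "TestResult",
    "chi_squared",
    "mann_whitney_u",
    "kruskal_wallis",
    "summarize_groups",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: Optional[int] = None


def chi_squared(counts, row_labels=None, col_labels=None) -> TestResult:
    """Plain Pearson chi-squared test of independence.

    ``statistic = sum (O-E)^2 / E`` with ``E = row_total * col_total / N``
    and ``df = (r-1)(c-1)``. No Yates correction and no minimum-expected-count
    enforcement. Rows or columns whose total is zero are dropped with a
    warning (their expected counts are undefined).
    """
    obs = np.asarray(counts, dtype=float)
    if obs.ndim != 2:
        raise ValueError("counts must be a 2-D table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row_keep = obs.sum(axis=1) > 0
    col_keep = obs.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        logger.warning(
            "dropping %d zero row(s) and %d zero column(s) from contingency table",
            int((~row_keep).sum()),
            int((~col_keep).sum()),
        )
        obs = obs[row_keep][:, col_keep]
    r, c = obs.shape
    if r < 2 or c < 2:
        raise ValueError("need at least 2 non-empty rows and columns")
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (r - 1) * (c - 1)
    p = float(chi2_dist.sf(stat, df))
    return TestResult(stat, p, "pearson-chi2", df)


def _u_statistics(a: np.ndarray, b: np.ndarray) -> tuple[float, float, np.ndarray]:
    """U for each sample via the rank formulation; also returns pooled ranks."""
    n_a, n_b = len(a), len(b)
    ranks = rankdata(np.concatenate([a, b]))
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0  # pairs where a beats b, ties half
    u_b = n_a * n_b - u_a
    return u_a, u_b, ranks


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], method: str = "normal"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    The reported statistic is ``min(U_a, U_b)``. ``method="normal"`` uses the
    tie-corrected normal approximation (appropriate for the cohort sizes this
    package targets); ``method="exact"`` enumerates all assignments of the
    pooled ranks (practical up to ~10 per sample, ties handled naturally by
    permuting the observed values).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    u_a, u_b, ranks = _u_statistics(a, b)
    u = min(u_a, u_b)
    n = n_a + n_b

    if method == "exact":
        pooled = np.concatenate([a, b])
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            ua, ub, _ = _u_statistics(pooled[mask], pooled[~mask])
            total += 1
            if min(ua, ub) <= u + 1e-12:
                count += 1
        return TestResult(float(u), count / total, "mann-whitney-exact")
    if method != "normal":
        raise ValueError(f"unknown method: {method!r}")

    mean_u = n_a * n_b / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:  # all observations identical
        return TestResult(float(mean_u), 1.0, "mann-whitney-normal")
    z = (u_a - mean_u) / math.sqrt(var_u)
    p = float(min(1.0, 2.0 * norm_dist.sf(abs(z))))
    return TestResult(float(u), p, "mann-whitney-normal")


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with tie correction.

    ``H = 12 / (N(N+1)) * sum n_g (Rbar_g - (N+1)/2)^2`` divided by
    ``1 - sum(t^3 - t) / (N^3 - N)``; p from the chi-squared distribution
    with k-1 degrees of freedom.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(g) == 0 for g in arrays):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = rankdata(pooled)
    mean_rank = (n + 1) / 2.0
    h = 0.0
    start = 0
    for g in arrays:
        r_g = ranks[start : start + len(g)]
        h += len(g) * (r_g.mean() - mean_rank) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    df = len(arrays) - 1
    if correction <= 0:  # every observation identical
        return TestResult(0.0, 1.0, "kruskal-wallis", df)
    h /= correction
    p = float(chi2_dist.sf(h, df))
    return TestResult(float(h), p, "kruskal-wallis", df)


def summarize_groups(
    subject_means: pd.DataFrame,
    group_col: str,
    feature_cols: Sequence[str],
) -> pd.DataFrame:
    """Group-comparison table of per-subject two-week feature means.

    One row per (variable, group) with mean and SD, plus the test statistic
    shared across that variable's groups: Mann-Whitney U for two groups,
    Kruskal-Wallis H for three or more. Groups without subjects are omitted
    with a warning. Output columns mirror the published summary layout:
    ``variable, group, n, mean, sd, statistic, stat_name, p_value``.
    """
    rows = []
    groups_present = [
        g for g, sub in subject_means.groupby(group_col, sort=True) if len(sub)
    ]
    for feature in feature_cols:
        samples: dict[str, np.ndarray] = {}
        for g in groups_present:
            vals = subject_means.loc[
                subject_means[group_col] == g, feature
            ].dropna()
            if len(vals):
                samples[g] = vals.to_numpy(dtype=float)
            else:
                logger.warning("group %r has no data for %s; omitted", g, feature)
        if len(samples) >= 3:
            res = kruskal_wallis(list(samples.values()))
            stat_name = "KW"
        elif len(samples) == 2:
            res = mann_whitney_u(*samples.values())
            stat_name = "U"
        else:
            res, stat_name = None, ""
        for g, vals in samples.items():
            rows.append(
                {
                    "variable": feature,
                    "group": g,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                    "statistic": res.statistic if res else np.nan,
                    "stat_name": stat_name,
                    "p_value": res.p_value if res else np.nan,
                }
            )
    return pd.DataFrame(rows)
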