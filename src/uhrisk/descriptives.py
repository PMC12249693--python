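"""Univariate baseline-table machinery and derived ABPM quantities.

Continuous variables are summarised as median (IQR) and compared with the
Mann-Whitney U test; binary variables as count (percent) and compared with
Pearson's chi-square, falling back to Fisher's exact test when any expected
cell is below 5.  Nocturnal dipping is the percentage fall of the nighttime
BP index relative to the daytime index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "dipping",
    "median_iqr",
    "mann_whitney",
    "chi_squared_or_fisher",
    "compare_groups",
]

_EXACT_MAX_N = 10  # combined size below which the U test enumerates exactly


@dataclass
class GroupComparison:
    """One row of a baseline table: summaries per group plus the test."""

    variable: str
    summary_total: str
    summary_a: str
    summary_b: str
    test: str
    statistic: float | None
    p_value: float

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def dipping(day_value: float, night_value: float) -> float:
    """Nocturnal dipping, percent: 100 * (day - night) / day.

    Negative values indicate a riser pattern (nighttime above daytime).
    """
    day = np.asarray(day_value, dtype=float)
    if np.any(day <= 0):
        raise ValueError("daytime BP must be positive")
    return 100.0 * (day - np.asarray(night_value, dtype=float)) / day


def median_iqr(values) -> tuple[float, float]:
    """Median and interquartile range (Q3 - Q1).

    Quartiles use linear interpolation between order statistics (numpy's
    default, the Hyndman-Fan type-7 rule), fixed here so reported IQRs are
    reproducible.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr needs a non-empty collection")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return float(med), float(q3 - q1)


def mann_whitney(group_a, group_b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of group_a, p).

    Uses the tie- and continuity-corrected normal approximation; for
    combined n <= 10 (``method="auto"``) the null distribution is
    enumerated exactly by permutation, which also handles ties.  ``method``
    may force ``"exact"`` or ``"asymptotic"``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        method = "exact" if a.size + b.size <= _EXACT_MAX_N else "asymptotic"
    if method == "exact":
        scipy_method = stats.PermutationMethod(n_resamples=np.inf)
    elif method == "asymptotic":
        scipy_method = "asymptotic"
    else:
        raise ValueError(f"unknown method {method!r}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method=scipy_method, use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def chi_squared_or_fisher(table_2x2) -> tuple[float | None, float, str]:
    """Compare a 2x2 count table; returns (statistic, p, test name).

    Pearson's chi-square without continuity correction when every expected
    count is >= 5; Fisher's exact two-sided test otherwise (its statistic
    slot is None).
    """
    table = np.asarray(table_2x2, dtype=float)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("expected a nonnegative 2x2 table")
    if not np.allclose(table, np.round(table)):
        raise ValueError("table entries must be integer counts")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("table has a zero margin")
    expected = np.outer(row, col) / table.sum()
    if (expected >= 5).all():
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p), "pearson-chi2"
    _, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
    return None, float(min(p, 1.0)), "fisher-exact"


def _fmt(x: float) -> str:
    return f"{x:.1f}"


def compare_groups(
    cohort: pd.DataFrame,
    continuous: list[str],
    binary: list[str],
    by: str = "uh",
) -> pd.DataFrame:
    """Build a baseline-characteristics table split by a binary column.

    One row per variable with per-group summaries, the test used, its
    statistic and p-value.
    """
    grp = cohort[by].astype(bool)
    a, b = cohort[~grp], cohort[grp]
    rows = []
    for var in continuous:
        med_t, iqr_t = median_iqr(cohort[var])
        med_a, iqr_a = median_iqr(a[var])
        med_b, iqr_b = median_iqr(b[var])
        u, p = mann_whitney(a[var], b[var])
        rows.append(GroupComparison(
            var, f"{_fmt(med_t)} ({_fmt(iqr_t)})",
            f"{_fmt(med_a)} ({_fmt(iqr_a)})", f"{_fmt(med_b)} ({_fmt(iqr_b)})",
            "mann-whitney", u, p,
        ))
    for var in binary:
        x = cohort[var].astype(bool)
        table = [[int((~grp & x).sum()), int((~grp & ~x).sum())],
                 [int((grp & x).sum()), int((grp & ~x).sum())]]
        stat, p, test = chi_squared_or_fisher(table)

        def pct(sub):
            n = len(sub)
            k = int(sub[var].astype(bool).sum())
            return f"{k} ({100.0 * k / n:.1f})" if n else "0 (0.0)"

        rows.append(GroupComparison(
            var, pct(cohort), pct(a), pct(b), test, stat, p,
        ))
    return pd.DataFrame([r.__dict__ for r in rows])
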