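"""Group comparisons and correlations for the clinical cohort.

The rank-sum test is authored here because its small-sample path must be an
exact permutation enumeration (including tied data, via midranks); scipy's
Mann-Whitney implementation serves as an independent cross-check in the
test suite rather than as the implementation. Pearson correlation and
Kaplan-Meier/log-rank are delegated to scipy and lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "WilcoxonResult",
    "wilcoxon_rank_sum",
    "pearson_correlation",
    "km_logrank",
    "summarize_groups",
    "drop_outliers_3iqr",
    "EXACT_ENUMERATION_MAX_N",
]

#: Largest pooled sample size for which the exact permutation distribution
#: of the rank-sum statistic is enumerated.
EXACT_ENUMERATION_MAX_N = 12


@dataclass
class WilcoxonResult:
    statistic: float  # rank-sum W of the first sample (midranks)
    pvalue: float
    method: str  # "exact" | "asymptotic"


def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled, method="average")


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test.

    For pooled n <= 12 the null distribution of W (sum of x's midranks) is
    enumerated over all C(n, n_x) group assignments, and the two-sided p is
    min(1, 2 * min-tail). Larger samples use the normal approximation with
    tie correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = x.size, y.size
    n = nx + ny
    ranks = _midranks(np.concatenate([x, y]))
    w = float(ranks[:nx].sum())

    if n <= EXACT_ENUMERATION_MAX_N:
        sums = np.array([sum(c) for c in combinations(ranks, nx)])
        total = sums.size
        lo = np.count_nonzero(sums <= w + 1e-9) / total
        hi = np.count_nonzero(sums >= w - 1e-9) / total
        p = min(1.0, 2.0 * min(lo, hi))
        return WilcoxonResult(statistic=w, pvalue=p, method="exact")

    mean_w = nx * (n + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_w = nx * ny / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var_w <= 0:
        return WilcoxonResult(statistic=w, pvalue=1.0, method="asymptotic")
    # continuity correction shrinks |W - E[W]| by 0.5
    z = (abs(w - mean_w) - 0.5) / np.sqrt(var_w)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(stats.norm.sf(z)))
    return WilcoxonResult(statistic=w, pvalue=p, method="asymptotic")


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p from the t reference
    distribution (t = r sqrt((n-2)/(1-r^2)))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("inputs must have nonzero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def km_logrank(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence,
) -> dict:
    """Kaplan-Meier curves for exactly two groups plus a log-rank test.

    Returns ``{"curves": {label: DataFrame(time, survival)}, "chi2": float,
    "pvalue": float}``. Curves are product-limit estimates with right
    censoring.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    levels = sorted(pd.unique(groups).tolist())
    if len(levels) != 2:
        raise ValueError("exactly two groups are required")
    curves = {}
    for level in levels:
        mask = groups == level
        if not events[mask].any():
            raise ValueError(f"group {level!r} has no events (all censored)")
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        sf = kmf.survival_function_
        curves[level] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    m0, m1 = groups == levels[0], groups == levels[1]
    res = logrank_test(times[m0], times[m1], events[m0], events[m1])
    return {"curves": curves, "chi2": float(res.test_statistic), "pvalue": float(res.p_value)}


def median_split(values: Sequence[float]) -> np.ndarray:
    """Boolean mask of the "high" arm of a median split; samples at the
    median go to the low arm (<= median)."""
    values = np.asarray(values, dtype=float)
    return values > np.median(values)


def summarize_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group median and min-max range of concentration and fragment
    size. Expects columns group, concentration_ng_per_ml,
    mean_fragment_size_bp."""
    if table.empty:
        raise ValueError("empty cohort table")
    out = table.groupby("group", sort=True).agg(
        n=("sample_id", "size"),
        conc_median=("concentration_ng_per_ml", "median"),
        conc_min=("concentration_ng_per_ml", "min"),
        conc_max=("concentration_ng_per_ml", "max"),
        size_median=("mean_fragment_size_bp", "median"),
        size_min=("mean_fragment_size_bp", "min"),
        size_max=("mean_fragment_size_bp", "max"),
    )
    return out.reset_index()


def drop_outliers_3iqr(values: Sequence[float]) -> np.ndarray:
    """Explicit outlier rule: keep points within 3x IQR of the quartiles.

    Returns the boolean keep-mask. Never applied silently by any other
    function in this module.
    """
    values = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return (values >= q1 - 3 * iqr) & (values <= q3 + 3 * iqr)
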