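"""Saccade-latency quartile analysis.

For each neuron and condition (value x direction), trials with a measured
saccade reaction time are sorted by latency and split into four contiguous
groups of (near-)equal size; the correlation between the group order
(1..4) and the group-mean window activity measures whether higher
pre-saccadic activity goes with faster saccades. The population-level
test asks whether the median per-neuron correlation differs from zero
(Wilcoxon signed-rank; exact null distribution at small n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def split_by_latency(rts: np.ndarray, n_groups: int = 4) -> np.ndarray:
    """Group assignment (0-based) after sorting by reaction time.

    Trials are sorted ascending by RT (ties broken by original order) and
    partitioned into ``n_groups`` contiguous blocks; when the count does
    not divide evenly the earliest (fastest) groups get the extra trials.
    Returns an array aligned with the input order.
    """
    rts = np.asarray(rts, dtype=float)
    n = rts.size
    if n < n_groups:
        raise ValueError("fewer trials than groups")
    order = np.argsort(rts, kind="stable")
    base, rem = divmod(n, n_groups)
    sizes = [base + (1 if g < rem else 0) for g in range(n_groups)]
    bounds = np.cumsum([0] + sizes)
    groups = np.empty(n, dtype=int)
    for g in range(n_groups):
        groups[order[bounds[g]:bounds[g + 1]]] = g
    return groups


def latency_activity_correlation(group_means: np.ndarray) -> float:
    """Pearson correlation of group order (1..k) against group-mean activity.

    Returns NaN (flagged degenerate) when the means have zero variance.
    """
    means = np.asarray(group_means, dtype=float)
    if not np.all(np.isfinite(means)):
        raise ValueError("group means must be finite")
    if np.ptp(means) == 0:
        return float("nan")
    r, _ = stats.pearsonr(np.arange(1, means.size + 1, dtype=float), means)
    return float(r)


@dataclass
class MedianRResult:
    median: float
    p: float
    n: int
    method: str  # exact | approx


def median_r_test(rs, exact_max_n: int = 25) -> MedianRResult:
    """Two-sided Wilcoxon signed-rank test of the per-neuron correlation
    coefficients against zero.

    Exact enumeration-based null for n <= ``exact_max_n`` (no ties/zeros),
    normal approximation with tie and zero handling otherwise.
    """
    rs = np.asarray([r for r in rs if np.isfinite(r)], dtype=float)
    if rs.size < 6:
        raise ValueError("need at least 6 defined correlation coefficients")
    if np.all(rs == 0):
        return MedianRResult(median=0.0, p=1.0, n=rs.size, method="exact")
    nonzero = rs[rs != 0]
    has_ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    if nonzero.size <= exact_max_n and not has_ties and nonzero.size == rs.size:
        res = stats.wilcoxon(rs, alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.wilcoxon(rs, alternative="two-sided", method="approx",
                             correction=True, zero_method="wilcox")
        method = "approx"
    return MedianRResult(median=float(np.median(rs)), p=float(res.pvalue),
                         n=rs.size, method=method)


def latency_correlation_table(
    per_trial: pd.DataFrame,
    n_groups: int = 4,
    activity_col: str = "activity",
    rt_col: str = "rt_ms",
    by: tuple[str, ...] = ("Neuron_ID", "value", "direction"),
) -> pd.DataFrame:
    """Per-(neuron, condition) latency-quartile correlations.

    ``per_trial`` has one row per trial with a measured RT and a window
    activity value. Conditions with fewer trials than groups, or with
    degenerate (zero-variance) group means, are skipped/flagged with NaN.
    """
    rows = []
    for keys, sub in per_trial.groupby(list(by), observed=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        rts = sub[rt_col].to_numpy(dtype=float)
        act = sub[activity_col].to_numpy(dtype=float)
        ok = np.isfinite(rts) & np.isfinite(act)
        rts, act = rts[ok], act[ok]
        if rts.size < n_groups:
            continue
        groups = split_by_latency(rts, n_groups)
        means = np.array([act[groups == g].mean() for g in range(n_groups)])
        r = latency_activity_correlation(means)
        rows.append((*keys, r, *means))
    cols = [*by, "r"] + [f"group{g + 1}_mean" for g in range(n_groups)]
    return pd.DataFrame(rows, columns=cols)
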