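"""Two-group differential expression: Wilcoxon rank-sum tests, log-ratio
effect sizes and rank-test-inversion confidence intervals.

The p-value comes from the Mann-Whitney/Wilcoxon rank-sum test (exact
enumeration when n+m <= 20 with no ties; normal approximation with tie and
continuity corrections otherwise). The effect size is the log2 ratio of
group means on the linear scale, log2(mean(2^x)/mean(2^y)), matching the
convention for log2-normalized expression; a difference-of-log-means mode is
also available. The confidence interval is a Hodges-Lehmann interval on the
log2-scale location shift obtained by inverting the rank-sum test: the set
of shifts delta for which x - delta vs y is not rejected at level 1 - conf.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm

_EXACT_LIMIT = 20  # exact null enumeration when n + m <= this and no ties


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first group
    p_value: float
    method: str  # "exact" or "asymptotic"


@dataclass(frozen=True)
class LogRatioResult:
    log2_ratio: float       # log2(mean(2^x) / mean(2^y)) (or log-mean difference)
    shift_estimate: float   # Hodges-Lehmann median of pairwise differences
    ci_low: float
    ci_high: float
    conf: float


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    ties = len(np.unique(np.concatenate([x, y]))) < x.size + y.size
    method = "exact" if (x.size + y.size <= _EXACT_LIMIT and not ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return RankSumResult(float(res.statistic), float(res.pvalue), method)


@lru_cache(maxsize=128)
def _u_null_cdf(n: int, m: int) -> np.ndarray:
    """Exact null CDF of the Mann-Whitney U statistic (no ties).

    cdf[u] = P(U <= u) for u = 0..n*m, from the standard count recurrence
    N(n, m, u) = N(n-1, m, u-m) + N(n, m-1, u).
    """
    U = n * m
    prev = np.zeros((n + 1, U + 1))
    prev[:, 0] = 1.0  # m' = 0
    for mm in range(1, m + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0
        for i in range(1, n + 1):
            shifted = np.zeros(U + 1)
            shifted[mm:] = cur[i - 1, : U + 1 - mm]
            cur[i] = shifted + prev[i]
        prev = cur
    pmf = prev[n] / prev[n].sum()
    return np.cumsum(pmf)


def _two_sided_p_of_u(u, n: int, m: int, exact: bool) -> np.ndarray:
    """Two-sided rank-sum p as a function of the U value alone (no ties).

    Vectorized over ``u``.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    U = n * m
    if exact:
        cdf = _u_null_cdf(n, m)
        ui = np.round(u).astype(int)
        lower = cdf[ui]
        upper = 1.0 - np.where(ui >= 1, cdf[np.maximum(ui - 1, 0)], 0.0)
        return np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    mu = U / 2.0
    sigma = np.sqrt(n * m * (n + m + 1) / 12.0)
    z = np.maximum((np.abs(u - mu) - 0.5) / sigma, 0.0)  # continuity correction
    return np.minimum(1.0, 2.0 * norm.sf(z))


def log_ratio_with_ci(x, y, conf: float = 0.99, mode: str = "ratio_of_means") -> LogRatioResult:
    """Log2 effect size with a rank-test-inversion confidence interval.

    Point estimate: ``ratio_of_means`` (default) computes
    log2(mean(2^x)/mean(2^y)) with x, y on the log2 scale;
    ``diff_of_log_means`` computes mean(x) - mean(y).

    The CI inverts the rank-sum test on a location shift of the log2 values:
    the p-value as a function of the shift delta is a step function changing
    only at the pairwise (Walsh) differences x_i - y_j, so the accepted
    region is read off the null distribution of U and the difference order
    statistics. Ends of an interval that never rejects are +-inf (warned).
    """
    if not (0.0 < conf < 1.0):
        raise ValueError(f"conf must be in (0,1), got {conf}")
    if mode not in ("ratio_of_means", "diff_of_log_means"):
        raise ValueError(f"unknown mode {mode!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("groups must be nonempty")
    if mode == "ratio_of_means":
        point = float(np.log2(np.mean(2.0 ** x) / np.mean(2.0 ** y)))
    else:
        point = float(np.mean(x) - np.mean(y))

    n, m = x.size, y.size
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    hl = float(np.median(diffs))
    alpha = 1.0 - conf
    exact = (n + m <= _EXACT_LIMIT) and (
        len(np.unique(np.concatenate([x, y]))) == n + m
    )
    # For delta strictly between diffs[k-1] and diffs[k] (1-indexed order
    # statistics), U of (x - delta) vs y equals n*m - k.
    U = n * m
    ks = np.arange(U + 1)
    accepted = _two_sided_p_of_u(U - ks, n, m, exact) > alpha
    idx = np.where(accepted)[0]
    if idx.size == 0:  # degenerate; should not occur for alpha < 1
        lo, hi = hl, hl
    else:
        a, b = int(idx[0]), int(idx[-1])
        if a == 0:
            lo = float("-inf")
            warnings.warn("sample sizes too small for a finite lower confidence bound")
        else:
            lo = float(diffs[a - 1])
        if b == U:
            hi = float("inf")
            warnings.warn("sample sizes too small for a finite upper confidence bound")
        else:
            hi = float(diffs[b])
    return LogRatioResult(point, hl, lo, hi, conf)


def mean_abs_difference(log2_ratios) -> float:
    """Mean absolute log2 ratio over a nonempty set of genes."""
    vals = np.asarray(log2_ratios, dtype=float)
    if vals.size == 0:
        raise ValueError("empty subset")
    return float(np.mean(np.abs(vals)))


def diff_expression_table(
    expr,
    group_a,
    group_b,
    conf: float = 0.99,
    star_p: float = 0.001,
    adjust: bool = False,
) -> pd.DataFrame:
    """Per-gene differential expression between two sample groups.

    ``expr`` is an ExpressionMatrix; ``group_a``/``group_b`` are sample-id
    lists. ``direction`` is "up"/"down" for genes significant at ``star_p``
    (the heatmap annotation threshold) and "ns" otherwise. ``adjust=True``
    appends a Benjamini-Hochberg column (off by default; the analysis
    convention applies no multiplicity correction).
    """
    frame = expr.to_frame()
    a = frame[list(group_a)].to_numpy()
    b = frame[list(group_b)].to_numpy()
    rows = []
    for i, gene in enumerate(expr.gene_ids):
        test = rank_sum_test(a[i], b[i])
        lr = log_ratio_with_ci(a[i], b[i], conf=conf)
        if test.p_value < star_p:
            direction = "up" if lr.log2_ratio > 0 else "down"
        else:
            direction = "ns"
        rows.append(
            {
                "gene": gene,
                "log2_ratio": lr.log2_ratio,
                "ci_low": lr.ci_low,
                "ci_high": lr.ci_high,
                "p_value": test.p_value,
                "method": test.method,
                "direction": direction,
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    if adjust:
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    return out
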