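"""Univariate comparison battery and group descriptives.

Covers the three tests used to compare carriers with wild-type individuals:
pooled-variance Student t (from raw samples or from printed mean/SD/n
summaries), the Mann-Whitney U test with midrank tie handling (exact
enumeration for small samples, tie-corrected normal approximation
otherwise), and the Pearson chi-square for 2x2 tables, by default without
continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "GroupSummary",
    "student_t",
    "student_t_from_summary",
    "mann_whitney_u",
    "u_statistic",
    "chi_square_2x2",
    "describe",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test_name: str
    df: float = float("nan")


@dataclass(frozen=True)
class GroupSummary:
    n: int
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    min: float
    max: float


# ---------------------------------------------------------------- Student t

def student_t_from_summary(mean1: float, sd1: float, n1: int,
                           mean2: float, sd2: float, n2: int,
                           welch: bool = False) -> TestResult:
    """Two-sided t test from group summaries, pooled variance by default."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd1 == 0 and sd2 == 0:
        # degenerate limits: identical constants -> no evidence; distinct -> certain
        if mean1 == mean2:
            return TestResult(0.0, 1.0, "student_t", n1 + n2 - 2)
        return TestResult(math.inf if mean1 > mean2 else -math.inf, 0.0,
                          "student_t", n1 + n2 - 2)
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                    equal_var=not welch)
    if welch:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        return TestResult(float(t), float(p), "welch_t", float(df))
    return TestResult(float(t), float(p), "student_t", float(n1 + n2 - 2))


def student_t(x, y, welch: bool = False) -> TestResult:
    """Two-sided t test from raw samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return student_t_from_summary(x.mean(), x.std(ddof=1), x.size,
                                  y.mean(), y.std(ddof=1), y.size, welch=welch)


# ------------------------------------------------------------- Mann-Whitney

def u_statistic(x, y) -> float:
    """Mann-Whitney U of x: number of (x, y) pairs with x > y, ties half.

    Computed through midranks, so U / (n1 n2) is the rank AUC of x against y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)


def _exact_u_pvalue(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p for U, conditional on the observed (tied) values.

    Enumerates the permutation distribution of the selected rank sum over all
    C(n1+n2, n1) group assignments by a counting DP over doubled midranks
    (midranks are multiples of 1/2, so doubling makes them integers).
    """
    n1 = x.size
    pooled = np.concatenate([x, y])
    r2 = np.rint(2.0 * sps.rankdata(pooled)).astype(int)  # doubled midranks
    smax = int(np.sort(r2)[-n1:].sum())
    smin = int(np.sort(r2)[:n1].sum())
    # f[k, s] = number of size-k subsets with doubled rank sum s
    f = np.zeros((n1 + 1, smax + 1))
    f[0, 0] = 1.0
    for r in r2:
        # one 0/1-knapsack item; numpy buffers the overlapping in-place add
        f[1:, r:] += f[:-1, : smax + 1 - r]
    total = f[n1, smin:].sum()
    # doubled observed rank sum of x
    s_obs = int(round(2.0 * (u_obs + n1 * (n1 + 1) / 2.0)))
    probs = f[n1] / total
    lo = probs[: s_obs + 1].sum()
    hi = probs[s_obs:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def mann_whitney_u(x, y, exact_limit: int = 400) -> TestResult:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Uses the exact conditional permutation distribution when
    ``n1 * n2 <= exact_limit`` (tie-aware, so identical samples give p = 1),
    and the tie-corrected normal approximation with continuity correction
    otherwise.  The reported statistic is U of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    u = u_statistic(x, y)
    if x.size * y.size <= exact_limit:
        return TestResult(u, _exact_u_pvalue(x, y, u), "mann_whitney")
    _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(u, float(p), "mann_whitney")


# --------------------------------------------------------------- chi-square

def chi_square_2x2(table, yates: bool = False) -> TestResult:
    """Pearson chi-square for a 2x2 table, df = 1.

    No continuity correction by default; ``yates=True`` applies it.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    (a, b), (c, d) = t
    n = t.sum()
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if min(margins) == 0:
        raise ValueError("all row and column marginals must be positive")
    num = abs(a * d - b * c)
    if yates:
        num = max(num - n / 2.0, 0.0)
    stat = n * num**2 / math.prod(margins)
    return TestResult(float(stat), float(sps.chi2.sf(stat, 1)), "chi_square", 1.0)


# ------------------------------------------------------------- descriptives

def summarize(values) -> GroupSummary:
    """Summary of one marker in one group (quartiles: linear interpolation
    between order statistics, the type-7 convention)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty group")
    q25, med, q75 = np.quantile(v, [0.25, 0.5, 0.75])
    return GroupSummary(n=int(v.size), mean=float(v.mean()),
                        sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
                        median=float(med), q25=float(q25), q75=float(q75),
                        min=float(v.min()), max=float(v.max()))


def describe(records: pd.DataFrame, group_by: str, markers=None) -> pd.DataFrame:
    """Per-group, per-marker descriptive table (one row per group x marker)."""
    from .cohort import MARKERS
    markers = list(markers) if markers is not None else list(MARKERS)
    rows = []
    for g, sub in records.groupby(group_by, sort=True):
        if sub.empty:
            continue
        for m in markers:
            s = summarize(sub[m])
            rows.append({"group": g, "marker": m, **s.__dict__})
    if not rows:
        raise ValueError("no non-empty groups to describe")
    return pd.DataFrame(rows)
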