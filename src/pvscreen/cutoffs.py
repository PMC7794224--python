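"""Empirical ROC curves and Youden-index optimal cut-offs.

Candidate thresholds are midpoints between consecutive distinct observed
values (plus one threshold below the minimum and one above the maximum, so
the degenerate operating points exist).  This is the convention that yields
half-unit cut-offs such as 248.5 from integer-valued platelet counts.

Two AUC routes are kept deliberately distinct — trapezoidal integration of
the empirical curve and the rank (Mann-Whitney) statistic — and must agree
to 1e-10; their equality is the module's internal oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as _ustats

__all__ = [
    "ROCCurve",
    "CutoffResult",
    "candidate_thresholds",
    "roc_curve",
    "auc_trapezoid",
    "auc_rank",
    "youden_optimal",
    "derive_all",
]


@dataclass
class ROCCurve:
    """Empirical operating points of one marker over candidate thresholds."""

    marker: str
    direction: str                    # 'greater': positives score high
    thresholds: np.ndarray            # strictly increasing
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_pos: int
    n_neg: int


@dataclass
class CutoffResult:
    """Youden-optimal operating point for one marker."""

    marker: str
    auc: float
    optimal_threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    direction: str = "greater"
    p_value: float | None = None
    excluded_by_univariate: bool = False


def candidate_thresholds(values) -> np.ndarray:
    """Midpoints between consecutive distinct sorted values, with one
    threshold below the minimum and one above the maximum."""
    v = np.unique(np.asarray(values, dtype=float))
    if v.size < 2:
        raise ValueError("need at least 2 distinct values")
    mids = (v[:-1] + v[1:]) / 2.0
    lo = v[0] - (v[1] - v[0]) / 2.0
    hi = v[-1] + (v[-1] - v[-2]) / 2.0
    return np.concatenate([[lo], mids, [hi]])


def _check_two_class(labels) -> tuple[np.ndarray, int, int]:
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    return y, n_pos, n_neg


def roc_curve(scores, labels, direction: str = "greater",
              marker: str = "score") -> ROCCurve:
    """Empirical ROC over all candidate thresholds.

    For direction='greater', sensitivity at threshold t is the fraction of
    positives with score > t and specificity the fraction of negatives with
    score <= t; mirrored for direction='less'.
    """
    if direction not in ("greater", "less"):
        raise ValueError(f"unknown direction {direction!r}")
    x = np.asarray(scores, dtype=float)
    y, n_pos, n_neg = _check_two_class(labels)
    if x.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if np.unique(x).size < 2:
        # all scores equal: only the two degenerate operating points exist
        t = np.array([x[0] - 0.5, x[0] + 0.5])
    else:
        t = candidate_thresholds(x)
    pos, neg = np.sort(x[y]), np.sort(x[~y])
    n_pos_gt = n_pos - np.searchsorted(pos, t, side="right")
    n_neg_gt = n_neg - np.searchsorted(neg, t, side="right")
    if direction == "greater":
        sens = n_pos_gt / n_pos
        spec = 1.0 - n_neg_gt / n_neg
    else:
        sens = 1.0 - n_pos_gt / n_pos
        spec = n_neg_gt / n_neg
    return ROCCurve(marker, direction, t, sens, spec, n_pos, n_neg)


def auc_trapezoid(curve: ROCCurve) -> float:
    """AUC by trapezoidal integration of sensitivity over 1 - specificity."""
    fpr = 1.0 - curve.specificity
    order = np.lexsort((curve.sensitivity, fpr))
    return float(np.trapezoid(curve.sensitivity[order], fpr[order]))


def auc_rank(scores, labels, direction: str = "greater") -> float:
    """Rank AUC: (# positive>negative pairs + 0.5 # tied pairs) / (n_pos n_neg)."""
    x = np.asarray(scores, dtype=float)
    y, n_pos, n_neg = _check_two_class(labels)
    u = _ustats.u_statistic(x[y], x[~y])
    a = u / (n_pos * n_neg)
    return float(a if direction == "greater" else 1.0 - a)


def youden_optimal(curve: ROCCurve, tie_break: str = "sensitivity") -> CutoffResult:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties in J are broken toward the higher-sensitivity threshold (the
    smallest threshold for direction='greater', the largest for 'less'),
    matching a screening test's sensitivity-first intent;
    ``tie_break='specificity'`` selects the opposite end.
    """
    if tie_break not in ("sensitivity", "specificity"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    j = curve.sensitivity + curve.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    want_low = (curve.direction == "greater") == (tie_break == "sensitivity")
    i = best[0] if want_low else best[-1]
    return CutoffResult(
        marker=curve.marker,
        auc=auc_trapezoid(curve),
        optimal_threshold=float(curve.thresholds[i]),
        sensitivity=float(curve.sensitivity[i]),
        specificity=float(curve.specificity[i]),
        youden_j=float(j[i]),
        direction=curve.direction,
    )


#: Markers compared with the Mann-Whitney U test (skewed cell counts);
#: the rest use the Student t test.
NONPARAMETRIC_MARKERS = frozenset({"wbc", "neutrophils", "platelets"})


def derive_all(stratum: pd.DataFrame, markers, alpha: float = 0.05,
               label_col: str = "jak2_positive", direction: str = "greater",
               tie_break: str = "sensitivity") -> list[CutoffResult]:
    """Univariate screen followed by ROC/Youden derivation per marker.

    Each marker is first compared between carriers and wild-type (t test, or
    Mann-Whitney for the skewed cell counts); only markers with p < alpha
    proceed to ROC analysis, the others are returned flagged
    ``excluded_by_univariate``.  ``direction='auto'`` picks per marker the
    direction with the larger rank AUC; the default forces 'greater' for all.
    """
    y, _, _ = _check_two_class(stratum[label_col])
    results: list[CutoffResult] = []
    for m in markers:
        x = stratum[m].to_numpy(dtype=float)
        if m in NONPARAMETRIC_MARKERS:
            test = _ustats.mann_whitney_u(x[y], x[~y])
        else:
            test = _ustats.student_t(x[y], x[~y])
        if test.p_value >= alpha:
            results.append(CutoffResult(
                marker=m, auc=float("nan"), optimal_threshold=float("nan"),
                sensitivity=float("nan"), specificity=float("nan"),
                youden_j=float("nan"), p_value=test.p_value,
                excluded_by_univariate=True))
            continue
        d = direction
        if direction == "auto":
            d = "greater" if auc_rank(x, y, "greater") >= 0.5 else "less"
        res = youden_optimal(roc_curve(x, y, d, marker=m), tie_break=tie_break)
        res.p_value = test.p_value
        results.append(res)
    return results


def results_frame(results: list[CutoffResult]) -> pd.DataFrame:
    """Tabulate CutoffResults (one row per marker)."""
    return pd.DataFrame([{
        "marker": r.marker, "auc": r.auc, "cutoff": r.optimal_threshold,
        "sensitivity": r.sensitivity, "specificity": r.specificity,
        "youden_j": r.youden_j, "p_value": r.p_value,
        "excluded_by_univariate": r.excluded_by_univariate,
    } for r in results])
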