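"""ROC/AUC primitives: rank-based AUC and DeLong variance/comparison.

The AUC of a score for a binary outcome equals the probability that a random
case outranks a random control (ties count one half) — the Mann-Whitney
statistic.  DeLong's method gives the sampling variance of that statistic and
a z-test for the difference between two AUCs measured on the same
individuals (correlated curves).
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["mann_whitney_auc", "delong_variance", "delong_test", "roc_curve_points"]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("AUC requires exactly two outcome classes")
    return (y == classes.max()).astype(int)


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def mann_whitney_auc(labels, scores) -> float:
    """AUC via midranks; exactly the concordant-pair count with ties = 1/2."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    r = _midrank(s)
    return (r[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


def _delong_components(y: np.ndarray, scores: np.ndarray):
    """Per-case and per-control placement values (structural components)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n          # per-case components
    v01 = 1.0 - (all_r[m:] - neg_r) / m    # per-control components
    return auc, v10, v01


def delong_variance(labels, scores) -> tuple[float, float]:
    """Return (auc, variance of auc) by DeLong's estimator."""
    y = _check_binary(labels)
    auc, v10, v01 = _delong_components(y, np.asarray(scores, dtype=float))
    var = np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    return float(auc), float(var)


def delong_test(labels, scores_a, scores_b) -> tuple[float, float]:
    """Two-sided test of equal AUC for two scores on the same individuals.

    Returns (delta_auc, p).  Accounts for the correlation induced by shared
    cases and controls.
    """
    y = _check_binary(labels)
    a_auc, a10, a01 = _delong_components(y, np.asarray(scores_a, dtype=float))
    b_auc, b10, b01 = _delong_components(y, np.asarray(scores_b, dtype=float))
    m, n = len(a10), len(a01)
    s10 = np.cov(np.vstack([a10, b10]), ddof=1)
    s01 = np.cov(np.vstack([a01, b01]), ddof=1)
    S = s10 / m + s01 / n
    var_diff = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    delta = a_auc - b_auc
    if var_diff <= 0:
        return float(delta), 1.0 if delta == 0 else 0.0
    z = delta / np.sqrt(var_diff)
    return float(delta), float(2 * stats.norm.sf(abs(z)))


def roc_curve_points(labels, scores) -> list:
    """(sensitivity, specificity, threshold) at every distinct cutoff.

    Positive call: score >= threshold.  Thresholds sweep the distinct score
    values descending, plus +inf (call nothing positive).
    """
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    n1 = y.sum()
    n0 = len(y) - n1
    pts = []
    for t in [np.inf] + sorted(np.unique(s), reverse=True):
        pred = s >= t
        sens = (pred & (y == 1)).sum() / n1
        spec = (~pred & (y == 0)).sum() / n0
        pts.append((float(sens), float(spec), float(t)))
    return pts
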