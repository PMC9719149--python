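"""ROC analysis and paired AUC comparison for plasma ratio markers.

Plasma 42/40 ratios are *lower* in amyloid-positive subjects, so the
default orientation treats lower scores as more positive-like; informative
markers then have AUC > 0.5.  The AUC is computed through the rank-sum
(Mann-Whitney) identity with ties counting one half; two markers measured
on the same subjects are compared with DeLong's nonparametric test based
on placement-value covariances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "PairedAUCComparison",
    "ClassificationStats",
    "auc",
    "roc_curve",
    "delong_paired_test",
    "classification_stats",
]

LOWER = "lower_is_positive"
HIGHER = "higher_is_positive"


@dataclass
class ROCResult:
    marker: str
    auc: float
    #: per-threshold operating points; thresholds on the original score scale
    curve: pd.DataFrame
    n_pos: int
    n_neg: int
    orientation: str


@dataclass(frozen=True)
class PairedAUCComparison:
    auc_a: float
    auc_b: float
    delta_auc: float
    variance: float
    z: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class ClassificationStats:
    threshold: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    youden_j: float


def _split(scores, labels, orientation: str) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if orientation not in (LOWER, HIGHER):
        raise ValueError(f"unknown orientation {orientation!r}")
    oriented = -scores if orientation == LOWER else scores
    pos = oriented[labels == "positive"]
    neg = oriented[labels == "negative"]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    return pos, neg


def auc(scores, labels, orientation: str = LOWER) -> float:
    """AUC via the rank-sum identity; tied score pairs count one half."""
    pos, neg = _split(scores, labels, orientation)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rank_sum_pos = ranks[: pos.size].sum()
    u = rank_sum_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_curve(scores, labels, orientation: str = LOWER, marker: str = "") -> ROCResult:
    """Full ROC curve with one operating point per distinct score.

    The trapezoidal area under the returned curve equals the rank-sum AUC
    (asserted internally, which pins down the tie handling).
    """
    pos, neg = _split(scores, labels, orientation)
    oriented = np.concatenate([pos, neg])
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    order = np.argsort(-oriented, kind="mergesort")
    oriented, y = oriented[order], y[order]
    distinct = np.r_[np.flatnonzero(np.diff(oriented)), oriented.size - 1]
    tps = np.cumsum(y)[distinct]
    fps = (distinct + 1) - tps
    sens = np.r_[0.0, tps / pos.size]
    fpr = np.r_[0.0, fps / neg.size]
    thresholds = np.r_[np.inf, oriented[distinct]]
    if np.isfinite(thresholds[1:]).all():
        # back to the original score scale
        raw = -thresholds if orientation == LOWER else thresholds
    else:
        raw = thresholds
    area = float(np.trapezoid(sens, fpr))
    rank_auc = auc(scores, labels, orientation)
    assert abs(area - rank_auc) < 1e-10, (area, rank_auc)
    curve = pd.DataFrame(
        {"threshold": raw, "sensitivity": sens, "specificity": 1.0 - fpr}
    )
    return ROCResult(
        marker=marker,
        auc=rank_auc,
        curve=curve,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
        orientation=orientation,
    )


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values via midranks.

    v10[i] = P(score of positive i beats a random negative), v01 likewise.
    """
    m, n = pos.size, neg.size
    both = np.concatenate([pos, neg])
    r_all = stats.rankdata(both)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01, float(v10.mean())


def delong_paired_test(scores_a, scores_b, labels, orientation: str = LOWER) -> PairedAUCComparison:
    """DeLong test for two correlated (same-subject) ROC AUCs.

    Two-sided normal p-value on (AUC_b - AUC_a) / sqrt(var), with the
    variance built from the placement-value covariance across markers.
    Identical placements (zero variance) yield p = 1 with a degenerate flag.
    """
    pos_a, neg_a = _split(scores_a, labels, orientation)
    pos_b, neg_b = _split(scores_b, labels, orientation)
    v10_a, v01_a, auc_a = _placements(pos_a, neg_a)
    v10_b, v01_b, auc_b = _placements(pos_b, neg_b)
    m, n = pos_a.size, neg_a.size
    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    delta = auc_b - auc_a
    if var <= 0:
        return PairedAUCComparison(auc_a, auc_b, delta, 0.0, 0.0, 1.0, degenerate=True)
    z = delta / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z)))
    return PairedAUCComparison(auc_a, auc_b, float(delta), float(var), float(z), p)


def classification_stats(
    scores,
    labels,
    orientation: str = LOWER,
    threshold: float | None = None,
) -> ClassificationStats:
    """Contingency-table rates at a threshold (default: Youden-optimal).

    With the default orientation a subject is called positive when its
    score is *at or below* the threshold (ties classified positive,
    mirroring the convention used for the CSF cut-off).  When ``threshold``
    is None the threshold maximizing Youden's J = sensitivity +
    specificity - 1 is chosen; J-ties resolve to the higher-sensitivity
    operating point.
    """
    scores_arr = np.asarray(scores, dtype=float)
    labels_arr = np.asarray(labels)
    _split(scores_arr, labels_arr, orientation)  # validation
    if threshold is None:
        candidates = np.unique(scores_arr)
        best = None
        for t in candidates:
            st = _stats_at(scores_arr, labels_arr, orientation, float(t))
            key = (st.youden_j, st.sensitivity)
            if best is None or key > best[0]:
                best = (key, st)
        return best[1]
    return _stats_at(scores_arr, labels_arr, orientation, float(threshold))


def _stats_at(scores, labels, orientation, threshold: float) -> ClassificationStats:
    if orientation == LOWER:
        called_pos = scores <= threshold
    else:
        called_pos = scores >= threshold
    is_pos = labels == "positive"
    tp = int(np.sum(called_pos & is_pos))
    fn = int(np.sum(~called_pos & is_pos))
    fp = int(np.sum(called_pos & ~is_pos))
    tn = int(np.sum(~called_pos & ~is_pos))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    acc = (tp + tn) / (tp + tn + fp + fn)
    return ClassificationStats(
        threshold=threshold,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        accuracy=acc,
        youden_j=sens + spec - 1.0,
    )
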