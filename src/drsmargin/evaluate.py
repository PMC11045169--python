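"""Classifier evaluation: MCC, ROC/AUC, operating points, CIs, and the
tumor-percentage-vs-margin-distance misclassification analysis.

The Matthews correlation coefficient is the headline metric because it
stays meaningful under the heavy class imbalance of margin data:

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

with the conventional value 0 when any denominator factor vanishes.

Two thresholds on the continuous malignancy score are computed and both
reported: the ROC operating point with minimum average misclassification
cost, and the threshold maximizing MCC.  Headline sensitivity/specificity
uses the cost-optimal point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "ROCCurve",
    "mcc",
    "confusion_counts",
    "roc_curve",
    "optimal_operating_point",
    "mcc_optimal_threshold",
    "aggregate_iterations",
    "misclassification_scatter",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient of a confusion matrix.

    Returns 0 when any of the four marginal totals is zero (the formula is
    undefined there).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def confusion_counts(scores: np.ndarray, labels: np.ndarray, threshold: float) -> ConfusionCounts:
    """Counts at a threshold; predicted malignant iff score >= threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    pred = scores >= threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & (labels == 1))),
        tn=int(np.sum(~pred & (labels == 0))),
        fp=int(np.sum(pred & (labels == 0))),
        fn=int(np.sum(~pred & (labels == 1))),
    )


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC by threshold sweep over unique scores; AUC by trapezoid rule.

    Equal scores are grouped into a single step.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def optimal_operating_point(
    curve: ROCCurve,
    cost_fp: float = 1.0,
    cost_fn: float = 1.0,
    prevalence: float = 0.5,
) -> tuple[float, float, float]:
    """Curve point with minimum expected misclassification cost.

    cost(point) = cost_fp * fpr * (1 - prevalence) + cost_fn * (1 - tpr) *
    prevalence; ties are broken toward higher sensitivity.  Returns
    (threshold, sensitivity, specificity).
    """
    cost = cost_fp * curve.fpr * (1.0 - prevalence) + cost_fn * (1.0 - curve.tpr) * prevalence
    best = np.flatnonzero(cost == cost.min())
    i = best[np.argmax(curve.tpr[best])]
    return float(curve.thresholds[i]), float(curve.tpr[i]), float(1.0 - curve.fpr[i])


def mcc_optimal_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold among unique scores maximizing MCC (ties: higher sensitivity).

    If the score set is degenerate (all values equal), every cut gives MCC
    0 and the common value is returned with a warning.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(int)
    if np.unique(labels).size < 2:
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    if uniq.size == 1:
        import warnings

        warnings.warn("all scores identical; MCC is 0 at every threshold", stacklevel=2)
        return float(uniq[0])
    best_thr, best_mcc, best_sens = None, -np.inf, -1.0
    for thr in uniq:
        c = confusion_counts(scores, labels, thr)
        m = mcc(c)
        sens = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
        if m > best_mcc or (m == best_mcc and sens > best_sens):
            best_thr, best_mcc, best_sens = float(thr), m, sens
    return best_thr


def aggregate_iterations(values: np.ndarray) -> tuple[float, float, tuple[float, float]]:
    """Mean, sample SD, and percentile 95% CI over iteration-level metrics."""
    values = np.asarray(values, float)
    if values.size < 2:
        raise ValueError("need >= 2 iterations to aggregate")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    lo, hi = np.percentile(values, [2.5, 97.5])
    return mean, sd, (float(lo), float(hi))


def misclassification_scatter(
    location_ids: np.ndarray,
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float,
    truth_by_location: dict[str, object],
) -> tuple[list[dict], float | None]:
    """Per-malignant-location scatter records and their Pearson correlation.

    Each record holds the location's mean tumor-margin distance, its tumor
    area percentage, and whether the classifier called it correctly at the
    given threshold.  The returned correlation is between tumor percentage
    and mean distance over all malignant locations (None when fewer than
    two malignant locations or either quantity is constant).
    """
    records = []
    for loc, s, lab in zip(location_ids, np.asarray(scores), np.asarray(labels).astype(int)):
        if lab != 1:
            continue
        truth = truth_by_location[loc]
        records.append(
            {
                "location_id": str(loc),
                "tumor_pct": float(truth.tumor_pct),
                "margin_distance_mean": float(truth.margin_distance_mean),
                "correct": bool(s >= threshold),
            }
        )
    if len(records) < 2:
        return records, None
    x = np.array([r["margin_distance_mean"] for r in records])
    y = np.array([r["tumor_pct"] for r in records])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        return records, None
    r, _ = pearsonr(x, y)
    return records, float(r)
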