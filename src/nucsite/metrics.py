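"""Confusion counts, threshold metrics, F-measure scan, ROC and AUC.

A regression score per residue is turned into a binary call with a
cutoff: positive iff score > cutoff (strictly).  Sweeping all cutoffs
gives the ROC curve of sensitivity against (1 − specificity); the area
under it (trapezoid rule, equal to the normalised Mann–Whitney U
statistic with ties counted ½) summarises performance independently of
the operating point.  Accuracy/sensitivity/specificity/precision and
F-measure are reported at the cutoff that maximises the F-measure.

F-measure defaults to the harmonic mean of precision and recall (the
conventional F1); a geometric-mean variant √(precision·recall) is
selectable via ``f_mode="geometric"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_at_cutoff",
    "threshold_metrics",
    "roc_curve",
    "roc_auc",
    "best_f_scan",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Threshold metrics in percent, plus AUC (%) and the cutoff used."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    auc: float = float("nan")
    cutoff: float = float("nan")
    f_mode: str = "harmonic"
    counts: ConfusionCounts | None = field(default=None, repr=False)


def _as_arrays(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    return scores, labels


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionCounts:
    """Tally TP/FP/TN/FN with the strict rule: positive iff score > cutoff."""
    scores, labels = _as_arrays(scores, labels)
    pred = scores > cutoff
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reported as NaN", name)
        return float("nan")
    return num / den


def _f_value(precision: float, recall: float, f_mode: str) -> float:
    if not (np.isfinite(precision) and np.isfinite(recall)):
        return float("nan")
    if f_mode == "harmonic":
        if precision + recall == 0:
            return float("nan")
        return 2.0 * precision * recall / (precision + recall)
    if f_mode == "geometric":
        return float(np.sqrt(precision * recall))
    raise ValueError(f"unknown f_mode {f_mode!r}")


def threshold_metrics(c: ConfusionCounts, f_mode: str = "harmonic") -> MetricsReport:
    """Standard definitions, reported in percent.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP);
    accuracy = (TP+TN)/total; precision = TP/(TP+FP);
    F = harmonic (default) or geometric mean of precision and recall.
    """
    sens = _safe_ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = _safe_ratio(c.tn, c.tn + c.fp, "specificity")
    acc = _safe_ratio(c.tp + c.tn, c.total, "accuracy")
    prec = _safe_ratio(c.tp, c.tp + c.fp, "precision")
    f = _f_value(prec, sens, f_mode)
    return MetricsReport(
        accuracy=100.0 * acc,
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        precision=100.0 * prec,
        f_measure=100.0 * f,
        f_mode=f_mode,
        counts=c,
    )


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(fpr, tpr, thresholds) over all distinct score cutoffs."""
    scores, labels = _as_arrays(scores, labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return fpr, tpr, thr


def roc_auc(scores, labels) -> float:
    """Trapezoid area under the ROC curve, in [0, 1].

    Equals the Mann–Whitney U statistic divided by n_pos·n_neg, with
    tied positive/negative score pairs contributing ½.
    """
    scores, labels = _as_arrays(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def best_f_scan(
    scores, labels, f_mode: str = "harmonic"
) -> tuple[float, MetricsReport]:
    """Maximise the F-measure over every distinct score cutoff.

    Returns the maximising cutoff (ties broken toward the lowest cutoff)
    together with the full metrics report at that cutoff, AUC included.
    """
    scores, labels = _as_arrays(scores, labels)
    order = np.argsort(scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    n = len(s_sorted)
    n_pos = int(l_sorted.sum())
    # suffix_pos[k] = number of positives among s_sorted[k:]
    suffix_pos = np.concatenate([np.cumsum(l_sorted[::-1])[::-1], [0]])
    uniq, first_idx, counts = np.unique(s_sorted, return_index=True, return_counts=True)
    idx_end = first_idx + counts          # predictions positive: scores > uniq[j]
    tp = suffix_pos[idx_end].astype(float)
    n_pred_pos = (n - idx_end).astype(float)
    fp = n_pred_pos - tp
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(n_pred_pos > 0, tp / n_pred_pos, np.nan)
        rec = tp / n_pos if n_pos else np.full_like(tp, np.nan)
        if f_mode == "harmonic":
            denom = prec + rec
            f = np.where(denom > 0, 2 * prec * rec / denom, np.nan)
        elif f_mode == "geometric":
            f = np.sqrt(prec * rec)
        else:
            raise ValueError(f"unknown f_mode {f_mode!r}")
    f_for_argmax = np.where(np.isfinite(f), f, -1.0)
    best = int(np.argmax(f_for_argmax))   # first (lowest) cutoff wins ties
    cutoff = float(uniq[best])
    report = threshold_metrics(confusion_at_cutoff(scores, labels, cutoff), f_mode)
    try:
        report.auc = 100.0 * roc_auc(scores, labels)
    except ValueError:
        pass
    report.cutoff = cutoff
    return cutoff, report
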