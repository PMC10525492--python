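"""Metrics, confusion matrices, fold aggregation, and montage comparison.

Binary metrics follow the usual seizure-detection conventions (the seizure
class is positive): Sn = TP/(TP+FN), Sp = TN/(TN+FP), precision = TP/(TP+FP),
F1 = 2*Prec*Sn/(Prec+Sn). Multigroup metrics are per-class one-vs-rest with
unweighted macro averages. A metric whose denominator is zero is reported as
NaN — an explicit "undefined" marker — never silently zero. Montage
comparisons use Welch's t-test, the Mann-Whitney U test, and D'Agostino and
Pearson's normality test on the per-fold metric values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetricsReport",
    "FoldSummary",
    "confusion_matrix",
    "binary_metrics",
    "multigroup_metrics",
    "compare_montages",
    "UNDEFINED",
]

#: Marker for a metric whose denominator is zero.
UNDEFINED = float("nan")


@dataclass
class MetricsReport:
    labels: tuple[str, ...]
    confusion: np.ndarray
    normalized_confusion: np.ndarray
    metrics: dict[str, float] = field(default_factory=dict)
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "confusion": self.confusion.tolist(),
            "normalized_confusion": self.normalized_confusion.tolist(),
            "metrics": self.metrics,
            "per_class": self.per_class,
        }


@dataclass
class FoldSummary:
    """Per-metric mean/std over k folds plus the raw per-fold values."""

    raw: dict[str, list[float]]

    @property
    def k(self) -> int:
        return len(next(iter(self.raw.values()))) if self.raw else 0

    def mean(self, metric: str) -> float:
        return float(np.nanmean(self.raw[metric]))

    def std(self, metric: str) -> float:
        return float(np.nanstd(self.raw[metric], ddof=1))

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.std(m)) for m in self.raw}


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def confusion_matrix(y_true, y_pred, labels) -> tuple[np.ndarray, np.ndarray]:
    """Counts matrix (row = true, column = predicted) and row-normalized form.

    Rows with zero support are all-zero in the normalized matrix.
    """
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    outside = sorted({y for y in list(y_true) + list(y_pred) if y not in index})
    if outside:
        raise ValueError(f"labels outside vocabulary: {outside}")
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    support = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        norm = np.where(support > 0, counts / np.maximum(support, 1), 0.0)
    return counts, norm


def binary_metrics(confusion: np.ndarray, positive_index: int = 1) -> MetricsReport:
    """Sensitivity/specificity/precision/F1/accuracy from a 2x2 matrix."""
    c = np.asarray(confusion)
    if c.shape != (2, 2):
        raise ValueError("binary_metrics needs a 2x2 confusion matrix")
    p, n = positive_index, 1 - positive_index
    tp, fn = c[p, p], c[p, n]
    tn, fp = c[n, n], c[n, p]
    sn = _safe_div(tp, tp + fn)
    sp = _safe_div(tn, tn + fp)
    prec = _safe_div(tp, tp + fp)
    f1 = (
        _safe_div(2 * prec * sn, prec + sn)
        if not (math.isnan(prec) or math.isnan(sn))
        else UNDEFINED
    )
    acc = _safe_div(tp + tn, c.sum())
    support = c.sum(axis=1, keepdims=True)
    norm = np.where(support > 0, c / np.maximum(support, 1), 0.0)
    return MetricsReport(
        labels=("neg", "pos") if positive_index == 1 else ("pos", "neg"),
        confusion=c,
        normalized_confusion=norm,
        metrics={
            "sensitivity": sn,
            "specificity": sp,
            "precision": prec,
            "recall": sn,
            "f1": f1,
            "accuracy": acc,
        },
    )


def multigroup_metrics(confusion: np.ndarray, labels=None) -> MetricsReport:
    """Per-class one-vs-rest metrics plus unweighted macro averages.

    Each class's ``accuracy_ovr`` is its one-vs-rest accuracy; ``recall_diag``
    is the diagonal (recall) view. Macro averages skip undefined entries.
    """
    c = np.asarray(confusion)
    k = c.shape[0]
    if c.shape != (k, k) or k < 2:
        raise ValueError("need a square KxK confusion matrix with K >= 2")
    labels = tuple(labels) if labels is not None else tuple(str(i) for i in range(k))
    total = c.sum()
    per_class = {}
    for i, lab in enumerate(labels):
        tp = c[i, i]
        fn = c[i].sum() - tp
        fp = c[:, i].sum() - tp
        tn = total - tp - fn - fp
        prec = _safe_div(tp, tp + fp)
        rec = _safe_div(tp, tp + fn)
        f1 = (
            _safe_div(2 * prec * rec, prec + rec)
            if not (math.isnan(prec) or math.isnan(rec))
            else UNDEFINED
        )
        per_class[lab] = {
            "precision": prec,
            "recall": rec,
            "f1": f1,
            "accuracy_ovr": _safe_div(tp + tn, total),
            "recall_diag": rec,
        }
    support = c.sum(axis=1, keepdims=True)
    norm = np.where(support > 0, c / np.maximum(support, 1), 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        macro = {
            f"macro_{m}": float(np.nanmean([pc[m] for pc in per_class.values()]))
            for m in ("precision", "recall", "f1", "accuracy_ovr")
        }
    macro["accuracy"] = _safe_div(np.trace(c), total)
    return MetricsReport(
        labels=labels, confusion=c, normalized_confusion=norm,
        metrics=macro, per_class=per_class,
    )


def compare_montages(values_a, values_b) -> dict:
    """Statistical comparison of per-fold metric values from two montages.

    Returns two-sided p-values of Welch's t-test and the Mann-Whitney U test,
    plus D'Agostino-Pearson normality p per sample (NaN with a warning below
    the test's minimum n).
    """
    from scipy import stats

    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per sample")
    out: dict = {}
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        out["welch_t"], out["welch_p"] = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out["welch_t"], out["welch_p"] = float(t), float(p)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    out["mannwhitney_u"], out["mannwhitney_p"] = float(u), float(p)
    for name, sample in (("normality_p_a", a), ("normality_p_b", b)):
        if sample.size < 8:  # scipy's minimum for the k2 test
            warnings.warn(
                f"sample of {sample.size} too small for the normality test"
            )
            out[name] = UNDEFINED
        else:
            out[name] = float(stats.normaltest(sample).pvalue)
    return out
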