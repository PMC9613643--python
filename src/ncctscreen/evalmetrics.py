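"""Confusion-matrix construction and the nine-metric evaluation suite.

Ischemic is the positive class throughout.  The eight ratio metrics are the
standard screening quantities (FP rate, FN rate, TN rate, sensitivity,
specificity, precision, accuracy, F-score); AUC is the concordance
probability of the score ranking (trapezoidal ROC area, half credit for
ties) and AP is the step-function summary of the precision–recall curve.
Metrics with a zero denominator are surfaced as *undefined* (None), never
coerced to 0, so fold averages stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "POSITIVE_LABEL",
    "ConfusionCounts",
    "MetricSet",
    "confusion",
    "compute_metrics",
    "roc_auc",
    "roc_curve_points",
    "precision_recall_points",
    "average_precision",
    "aggregate_folds",
]

POSITIVE_LABEL = "ischemic"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class MetricSet:
    """The nine evaluation metrics; None marks an undefined (0/0) entry."""

    fp_rate: float | None = None
    fn_rate: float | None = None
    tn_rate: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    accuracy: float | None = None
    f_score: float | None = None
    auc: float | None = None
    ap: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _to_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "USO":
        return np.asarray([x == POSITIVE_LABEL for x in arr], dtype=bool)
    return arr.astype(bool)


def confusion(predictions, truths) -> ConfusionCounts:
    """Count TP/FP/TN/FN; accepts 'ischemic'/'normal' strings or booleans."""
    p = _to_binary(predictions)
    t = _to_binary(truths)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} predictions vs {t.shape} truths")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """The eight ratio metrics from a confusion table.

    fp_rate = FP/(FP+TN), fn_rate = FN/(FN+TP), tn_rate = TN/(TN+FP),
    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    precision = TP/(TP+FP), accuracy = (TP+TN)/total,
    F = 2*precision*sensitivity/(precision+sensitivity).
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics from an empty confusion table")
    sens = _ratio(c.tp, c.tp + c.fn)
    prec = _ratio(c.tp, c.tp + c.fp)
    if prec is None or sens is None or prec + sens == 0:
        f = None
    else:
        f = 2.0 * prec * sens / (prec + sens)
    return MetricSet(
        fp_rate=_ratio(c.fp, c.fp + c.tn),
        fn_rate=_ratio(c.fn, c.fn + c.tp),
        tn_rate=_ratio(c.tn, c.tn + c.fp),
        sensitivity=sens,
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=prec,
        accuracy=(c.tp + c.tn) / c.total,
        f_score=f,
    )


def roc_auc(scores, truths) -> float | None:
    """AUC as P(score of random positive > score of random negative), ties ½.

    Equivalent to the trapezoidal area under the empirical ROC curve.
    Returns None when only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    t = _to_binary(truths)
    n_pos, n_neg = int(t.sum()), int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    # rank-sum (Mann–Whitney) formulation with midranks for ties
    order = np.argsort(s, kind="mergesort")
    ranks = np.empty(len(s), dtype=float)
    sorted_s = s[order]
    i = 0
    while i < len(s):
        j = i
        while j + 1 < len(s) and sorted_s[j + 1] == sorted_s[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    rank_sum_pos = ranks[t].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve_points(scores, truths) -> tuple[np.ndarray, np.ndarray]:
    """(fpr, tpr) points of the empirical ROC, for plotting/export."""
    s = np.asarray(scores, dtype=float)
    t = _to_binary(truths)
    order = np.argsort(-s, kind="mergesort")
    s, t = s[order], t[order]
    distinct = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], dtype=int)
    idx = np.concatenate((distinct, [len(s) - 1]))
    tps = np.cumsum(t)[idx]
    fps = np.cumsum(~t)[idx]
    tpr = np.concatenate(([0.0], tps / max(t.sum(), 1)))
    fpr = np.concatenate(([0.0], fps / max((~t).sum(), 1)))
    return fpr, tpr


def precision_recall_points(scores, truths) -> tuple[np.ndarray, np.ndarray]:
    """(recall, precision) at each distinct descending score threshold."""
    s = np.asarray(scores, dtype=float)
    t = _to_binary(truths)
    order = np.argsort(-s, kind="mergesort")
    s, t = s[order], t[order]
    distinct = np.flatnonzero(np.diff(s)) if len(s) > 1 else np.array([], dtype=int)
    idx = np.concatenate((distinct, [len(s) - 1]))
    tps = np.cumsum(t)[idx]
    fps = np.cumsum(~t)[idx]
    recall = tps / max(t.sum(), 1)
    precision = tps / (tps + fps)
    return recall, precision


def average_precision(scores, truths) -> float | None:
    """AP = Σ_n (R_n − R_{n−1}) · P_n over descending score thresholds."""
    t = _to_binary(truths)
    if t.sum() == 0:
        return None
    recall, precision = precision_recall_points(scores, truths)
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, precision):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)


def aggregate_folds(per_fold: list[MetricSet], warn=None) -> dict[str, tuple[float, float]]:
    """Mean ± sample SD per metric across folds, skipping undefined entries.

    Returns {metric: (mean, sd)}; a metric undefined in every fold is
    omitted.  ``warn`` (callable) is invoked once per metric that had
    undefined entries.
    """
    if not per_fold:
        raise ValueError("no folds to aggregate")
    if len(per_fold) < 2:
        raise ValueError("need at least two folds for a mean ± SD summary")
    out: dict[str, tuple[float, float]] = {}
    for name in per_fold[0].as_dict():
        vals = [m.as_dict()[name] for m in per_fold]
        defined = [v for v in vals if v is not None]
        if len(defined) < len(vals) and warn is not None:
            warn(f"metric {name}: {len(vals) - len(defined)} undefined fold value(s) skipped")
        if not defined:
            continue
        mean = float(np.mean(defined))
        sd = float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
        out[name] = (mean, sd)
    return out
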