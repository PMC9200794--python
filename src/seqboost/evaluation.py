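"""Seven-metric evaluation, stratified cross-validation and batch averaging.

Threshold metrics (ACC, precision, SEN, F1, MCC, SPC, FPR) come from the
confusion counts at a 0.5 probability cutoff; a zero denominator yields 0
with the metric name recorded in ``flags``.  AUC is the trapezoidal area
under the tie-grouped ROC curve and AUPR the recall-step-weighted sum of
precisions.  ``cross_validate`` averages per-fold metrics arithmetically;
``batch_evaluate`` repeats that for each negative batch paired with the
full positive set and averages the batch reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import gbdt, selection as fsel
from .errors import UndefinedMetricError

METRIC_FIELDS = ("acc", "sen", "spc", "f1", "mcc", "auc", "aupr", "precision", "fpr")


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    acc: float = 0.0
    sen: float = 0.0
    spc: float = 0.0
    f1: float = 0.0
    mcc: float = 0.0
    auc: float = 0.0
    aupr: float = 0.0
    precision: float = 0.0
    fpr: float = 0.0
    counts: Optional[ConfusionCounts] = None
    flags: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_FIELDS}


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch between labels and predictions")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def _safe_div(num: float, den: float, name: str, flags: set[str]) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def threshold_metrics(c: ConfusionCounts) -> MetricsReport:
    """Confusion-count metrics; degenerate denominators give flagged zeros."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    flags: set[str] = set()
    acc = (c.tp + c.tn) / c.total
    precision = _safe_div(c.tp, c.tp + c.fp, "precision", flags)
    sen = _safe_div(c.tp, c.tp + c.fn, "sen", flags)
    spc = _safe_div(c.tn, c.tn + c.fp, "spc", flags)
    f1 = _safe_div(c.tp, c.tp + 0.5 * (c.fn + c.fp), "f1", flags)
    mcc_den = np.sqrt(
        float(c.fp + c.tp) * (c.fn + c.tp) * (c.fp + c.tn) * (c.fn + c.tn)
    )
    mcc = _safe_div(c.tp * c.tn - c.fp * c.fn, mcc_den, "mcc", flags)
    fpr = 1.0 - spc
    return MetricsReport(
        acc=acc,
        sen=sen,
        spc=spc,
        f1=f1,
        mcc=mcc,
        precision=precision,
        fpr=fpr,
        counts=c,
        flags=flags,
    )


def _roc_points(y_true: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC (FPR, TPR) points over descending tie-grouped thresholds."""
    order = np.argsort(-scores, kind="stable")
    y = y_true[order]
    s = scores[order]
    # indices where a threshold block ends (last occurrence of each value)
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    ends = np.r_[distinct, y.size - 1]
    tps = np.cumsum(y)[ends]
    fps = np.cumsum(1 - y)[ends]
    n_pos = y.sum()
    n_neg = y.size - n_pos
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    return fpr, tpr


def roc_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve (equals the rank statistic)."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(y_true).size < 2:
        raise UndefinedMetricError("AUC needs both classes")
    fpr, tpr = _roc_points(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


def aupr(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Area under precision-recall: sum over descending thresholds of
    (Recall_n - Recall_{n-1}) * Precision_n."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if np.unique(y_true).size < 2:
        raise UndefinedMetricError("AUPR needs both classes")
    order = np.argsort(-scores, kind="stable")
    y = y_true[order]
    s = scores[order]
    distinct = np.flatnonzero(np.diff(s)) if s.size > 1 else np.array([], dtype=int)
    ends = np.r_[distinct, y.size - 1]
    tps = np.cumsum(y)[ends]
    fps = np.cumsum(1 - y)[ends]
    n_pos = y.sum()
    recall = tps / n_pos
    prec = tps / (tps + fps)
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * prec))


def average_reports(reports: list[MetricsReport]) -> MetricsReport:
    """Arithmetic mean of every metric field; flags and counts unioned/summed."""
    if not reports:
        raise ValueError("no reports to average")
    avg = MetricsReport()
    for name in METRIC_FIELDS:
        setattr(avg, name, float(np.mean([getattr(r, name) for r in reports])))
    counts = ConfusionCounts()
    for r in reports:
        if r.counts is not None:
            counts.tp += r.counts.tp
            counts.tn += r.counts.tn
            counts.fp += r.counts.fp
            counts.fn += r.counts.fn
        avg.flags |= r.flags
    avg.counts = counts
    return avg


def evaluate_scores(y_true: np.ndarray, proba: np.ndarray, threshold: float = 0.5) -> MetricsReport:
    """Full seven-metric report from predicted probabilities."""
    y_true = np.asarray(y_true, dtype=int)
    proba = np.asarray(proba, dtype=float)
    report = threshold_metrics(confusion(y_true, (proba >= threshold).astype(int)))
    report.auc = roc_auc(y_true, proba)
    report.aupr = aupr(y_true, proba)
    return report


@dataclass
class CVPlan:
    k: int = 10
    stratified: bool = True
    seed: int = 0


FitPredict = Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]


def _default_fit_predict(gbdt_params: dict, selection_params: dict | None) -> FitPredict:
    """Train-and-score closure: optional in-fold importance selection, then
    the gradient-boosted tree model."""

    def fit_predict(X_tr: np.ndarray, y_tr: np.ndarray, X_te: np.ndarray) -> np.ndarray:
        X_tr = fsel.impute_missing(X_tr)
        X_te = fsel.impute_missing(X_te)
        if selection_params is not None:
            ranking = fsel.fit_importance(X_tr, y_tr, **selection_params)
            mask = fsel.select(ranking, rule="nonzero")
            if mask.selected_count:
                X_tr = X_tr[:, mask.keep]
                X_te = X_te[:, mask.keep]
        model = gbdt.train(X_tr, y_tr, **gbdt_params)
        return gbdt.predict_proba(model, X_te)

    return fit_predict


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    plan: CVPlan,
    fit_predict: FitPredict | None = None,
    gbdt_params: dict | None = None,
    selection_params: dict | None = None,
) -> tuple[MetricsReport, list[MetricsReport]]:
    """Stratified k-fold CV; per-fold metrics averaged arithmetically."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    class_sizes = np.bincount(y)
    if plan.k > class_sizes[class_sizes > 0].min():
        raise ValueError(f"k={plan.k} exceeds smallest class size")
    if fit_predict is None:
        fit_predict = _default_fit_predict(gbdt_params or {}, selection_params)
    splitter = StratifiedKFold(
        n_splits=plan.k, shuffle=True, random_state=plan.seed
    )
    fold_reports: list[MetricsReport] = []
    for train_idx, test_idx in splitter.split(X, y):
        proba = fit_predict(X[train_idx], y[train_idx], X[test_idx])
        fold_reports.append(evaluate_scores(y[test_idx], proba))
    return average_reports(fold_reports), fold_reports
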