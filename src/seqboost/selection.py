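"""Boosted-tree feature ranking and selection.

A real-valued AdaBoost (SAMME.R) ensemble of depth-limited trees is fit to
the labeled feature matrix; each feature's score is its impurity-decrease
importance averaged over the ensemble.  Selection keeps either every
feature with a positive score (default) or the top k by rank.

The SAMME.R boosting loop is written out here because recent scikit-learn
releases removed the real-valued variant from ``AdaBoostClassifier``; the
base learners remain scikit-learn decision trees.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .errors import DegenerateLabelsError

log = logging.getLogger(__name__)


@dataclass
class ImportanceRanking:
    scores: np.ndarray  # non-negative, sums to 1 when any score > 0
    order: np.ndarray  # feature indices, descending score, ties by index
    rounds: int
    depth: int
    seed: int


@dataclass
class SelectionMask:
    keep: np.ndarray  # boolean per feature

    @property
    def selected_count(self) -> int:
        return int(self.keep.sum())

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.keep)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "selected_count": self.selected_count,
                    "indices": self.indices.tolist(),
                }
            )
        )


def impute_missing(X: np.ndarray) -> np.ndarray:
    """Column-mean imputation of NaNs (all-NaN columns become 0)."""
    X = np.array(X, dtype=float)
    nan_cols = np.flatnonzero(np.isnan(X).any(axis=0))
    for j in nan_cols:
        col = X[:, j]
        finite = col[~np.isnan(col)]
        fill = finite.mean() if finite.size else 0.0
        col[np.isnan(col)] = fill
    if nan_cols.size:
        log.debug("imputed %d columns with NaNs", nan_cols.size)
    return X


def fit_importance(
    X: np.ndarray,
    y: np.ndarray,
    rounds: int = 50,
    depth: int = 1,
    seed: int = 0,
) -> ImportanceRanking:
    """SAMME.R boosting with per-feature impurity-decrease importances.

    Each round fits a depth-``depth`` tree to the current sample weights,
    then reweights samples by the real-valued (class-probability) update
    with probabilities clipped away from 0/1.  Deterministic given ``seed``.
    """
    X = impute_missing(X)
    y = np.asarray(y, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if X.shape[0] < 4:
        raise ValueError("need at least 4 samples")
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateLabelsError("feature selection needs both classes")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")

    n, d = X.shape
    n_classes = classes.size
    rng = np.random.default_rng(seed)
    w = np.full(n, 1.0 / n)
    # SAMME.R coding: y_k = 1 for the true class, -1/(K-1) otherwise.
    coding = np.full((n, n_classes), -1.0 / (n_classes - 1))
    for k, cls in enumerate(classes):
        coding[y == cls, k] = 1.0

    eps = np.finfo(float).eps
    importances = np.zeros(d)
    fitted = 0
    for _ in range(rounds):
        tree = DecisionTreeClassifier(
            max_depth=depth,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X, y, sample_weight=w)
        proba = np.clip(tree.predict_proba(X), eps, 1.0)
        importances += tree.feature_importances_
        fitted += 1
        # w_i <- w_i * exp(-((K-1)/K) * sum_k y_ik log p_ik)
        exponent = -((n_classes - 1.0) / n_classes) * np.einsum(
            "ik,ik->i", coding, np.log(proba)
        )
        w *= np.exp(np.clip(exponent, -50, 50))
        total = w.sum()
        if not np.isfinite(total) or total <= 0:
            break
        w /= total

    scores = importances / fitted
    total = scores.sum()
    if total > 0:
        scores = scores / total
    order = np.argsort(-scores, kind="stable")
    return ImportanceRanking(
        scores=scores, order=order, rounds=rounds, depth=depth, seed=seed
    )


def select(
    ranking: ImportanceRanking, rule: str = "nonzero", k: int | None = None
) -> SelectionMask:
    """Build a keep-mask from a ranking.

    ``nonzero`` keeps every feature with score > 0; ``top-k`` keeps the k
    best by rank (ties broken by ascending feature index).
    """
    scores = ranking.scores
    if rule == "nonzero":
        keep = scores > 0
        if not keep.any():
            warnings.warn("all importance scores are zero: empty selection")
    elif rule == "top-k":
        if k is None or k <= 0:
            raise ValueError("top-k selection needs k >= 1")
        if k > scores.size:
            raise ValueError(f"k={k} exceeds feature count {scores.size}")
        keep = np.zeros(scores.size, dtype=bool)
        keep[ranking.order[:k]] = True
    else:
        raise ValueError(f"unknown selection rule: {rule!r}")
    return SelectionMask(keep=keep)


def write_importance_table(
    ranking: ImportanceRanking, names: list[str], path: str | Path
) -> None:
    with open(path, "w") as handle:
        handle.write("feature\tscore\trank\n")
        for rank, idx in enumerate(ranking.order, start=1):
            handle.write(f"{names[idx]}\t{ranking.scores[idx]:.10g}\t{rank}\n")
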