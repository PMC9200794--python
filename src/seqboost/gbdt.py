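"""Gradient-boosted regression trees with logistic loss, from first
principles.

Labels are stored as {0,1}; internally the +/-1 view y~ = 2y - 1 drives the
loss.  The model score is H(x) = h0 + lr * sum_m v_m(x) where h0 is the
half log-odds of the positive class and each tree's leaf values solve the
one-dimensional logistic argmin by safeguarded Newton-Raphson.  Predicted
probability is sigmoid(2 H(x)) so that an empty model (M = 0) predicts the
training prevalence exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DegenerateLabelsError, ShapeError

SCORE_CLIP = 50.0
LEAF_VALUE_CLIP = 4.0


@dataclass
class RegressionTree:
    """Flat-array binary tree; ``feature[i] == -1`` marks a leaf."""

    feature: list[int] = field(default_factory=list)
    threshold: list[float] = field(default_factory=list)
    left: list[int] = field(default_factory=list)
    right: list[int] = field(default_factory=list)
    value: list[float] = field(default_factory=list)

    def _new_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(0.0)
        return len(self.feature) - 1

    @property
    def n_leaves(self) -> int:
        return sum(1 for f in self.feature if f == -1)

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node index for every row."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        feat = np.array(self.feature)
        thr = np.array(self.threshold)
        left = np.array(self.left)
        right = np.array(self.right)
        nodes = np.zeros(X.shape[0], dtype=np.int64)
        while True:
            idx = np.flatnonzero(feat[nodes] != -1)
            if not idx.size:
                return nodes
            cur = nodes[idx]
            go_left = X[idx, feat[cur]] <= thr[cur]
            nodes[idx] = np.where(go_left, left[cur], right[cur])

    def predict(self, X: np.ndarray) -> np.ndarray:
        values = np.array(self.value)
        return values[self.apply(X)]


@dataclass
class GBDTModel:
    h0: float
    trees: list[RegressionTree]
    lr: float
    loss_curve: list[float] = field(default_factory=list)
    n_features: int | None = None


def init_score(y: np.ndarray) -> float:
    """Initial constant score: half the log-odds of the positive class."""
    y = np.asarray(y, dtype=float)
    pos = y.sum()
    neg = (1.0 - y).sum()
    if pos == 0 or neg == 0:
        raise DegenerateLabelsError("initial score needs both classes")
    return 0.5 * float(np.log(pos / neg))


def pseudo_residuals(y_pm: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Negative logistic-loss gradient r_i = y~_i / (1 + exp(y~_i h_i))."""
    y_pm = np.asarray(y_pm, dtype=float)
    h = np.clip(np.asarray(h, dtype=float), -SCORE_CLIP, SCORE_CLIP)
    return y_pm / (1.0 + np.exp(y_pm * h))


def logistic_loss(y_pm: np.ndarray, h: np.ndarray) -> float:
    h = np.clip(np.asarray(h, dtype=float), -SCORE_CLIP, SCORE_CLIP)
    return float(np.mean(np.log1p(np.exp(-np.asarray(y_pm, dtype=float) * h))))


def _best_split(
    x: np.ndarray, r: np.ndarray, min_leaf: int
) -> tuple[float, float] | None:
    """Best threshold on one feature by squared-error reduction.

    Returns (gain, threshold) or None.  Thresholds are midpoints between
    distinct consecutive sorted values; ``min_leaf`` rows required per side.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    rs = r[order]
    n = xs.size
    if n < 2 * min_leaf:
        return None
    csum = np.cumsum(rs)
    total = csum[-1]
    # candidate split after position i (1-based count on the left)
    counts = np.arange(1, n)
    valid = (counts >= min_leaf) & (n - counts >= min_leaf) & (xs[1:] > xs[:-1])
    if not valid.any():
        return None
    left_sum = csum[:-1]
    gain = left_sum**2 / counts + (total - left_sum) ** 2 / (n - counts)
    gain = np.where(valid, gain, -np.inf)
    best = int(np.argmax(gain))
    base = total**2 / n
    if gain[best] - base <= 1e-12:
        return None
    threshold = 0.5 * (xs[best] + xs[best + 1])
    return float(gain[best] - base), threshold


def fit_tree(
    X: np.ndarray, r: np.ndarray, max_depth: int = 3, min_leaf: int = 5
) -> tuple[RegressionTree, np.ndarray]:
    """Greedy least-squares regression tree on the residuals.

    Leaves initially predict the region mean of ``r``; returns the tree and
    the per-row leaf assignment.  Ties in split gain resolve to the lowest
    feature index (deterministic).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    r = np.asarray(r, dtype=float)
    if X.shape[0] != r.size:
        raise ShapeError("X rows and residual count differ")
    tree = RegressionTree()

    def grow(rows: np.ndarray, depth: int) -> int:
        node = tree._new_node()
        tree.value[node] = float(r[rows].mean())
        if depth >= max_depth or rows.size < 2 * min_leaf:
            return node
        best_gain, best_feat, best_thr = 0.0, -1, 0.0
        for j in range(X.shape[1]):
            found = _best_split(X[rows, j], r[rows], min_leaf)
            if found is not None and found[0] > best_gain + 1e-12:
                best_gain, best_feat, best_thr = found[0], j, found[1]
        if best_feat == -1:
            return node
        go_left = X[rows, best_feat] <= best_thr
        tree.feature[node] = best_feat
        tree.threshold[node] = best_thr
        tree.left[node] = grow(rows[go_left], depth + 1)
        tree.right[node] = grow(rows[~go_left], depth + 1)
        return node

    grow(np.arange(X.shape[0]), 0)
    return tree, tree.apply(X)


def _newton_leaf_value(y_pm: np.ndarray, h: np.ndarray) -> float:
    """argmin_v sum log(1 + exp(-y~ (h + v))) by safeguarded Newton from 0."""
    v = 0.0
    for _ in range(25):
        r = pseudo_residuals(y_pm, h + v)
        grad = r.sum()  # = -dLoss/dv
        hess = (np.abs(r) * (1.0 - np.abs(r))).sum()
        if hess < 1e-12:
            # saturated leaf: every residual at +/-1
            return float(np.clip(np.sign(grad) * LEAF_VALUE_CLIP, -LEAF_VALUE_CLIP, LEAF_VALUE_CLIP))
        step = grad / hess
        v += step
        if abs(step) < 1e-8:
            break
    return float(np.clip(v, -LEAF_VALUE_CLIP, LEAF_VALUE_CLIP))


def leaf_values(
    tree: RegressionTree,
    leaf_assign: np.ndarray,
    y_pm: np.ndarray,
    h: np.ndarray,
) -> RegressionTree:
    """Replace each leaf's mean-residual value with the logistic argmin."""
    y_pm = np.asarray(y_pm, dtype=float)
    h = np.asarray(h, dtype=float)
    for leaf in np.unique(leaf_assign):
        rows = leaf_assign == leaf
        tree.value[int(leaf)] = _newton_leaf_value(y_pm[rows], h[rows])
    return tree


def train(
    X: np.ndarray,
    y: np.ndarray,
    rounds: int = 100,
    lr: float = 0.1,
    max_depth: int = 3,
    min_leaf: int = 5,
    seed: int = 0,
) -> GBDTModel:
    """Boost ``rounds`` regression trees on the logistic loss.

    Fully deterministic (the greedy tree builder has no randomness); the
    ``seed`` argument is accepted for interface symmetry.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    if not 0.0 < lr <= 1.0:
        raise ValueError("learning rate must be in (0, 1]")
    h0 = init_score(y)
    y_pm = 2.0 * y - 1.0
    h = np.full(y.size, h0)
    trees: list[RegressionTree] = []
    losses = [logistic_loss(y_pm, h)]
    for _ in range(rounds):
        r = pseudo_residuals(y_pm, h)
        tree, assign = fit_tree(X, r, max_depth=max_depth, min_leaf=min_leaf)
        tree = leaf_values(tree, assign, y_pm, h)
        h = h + lr * np.array(tree.value)[assign]
        trees.append(tree)
        losses.append(logistic_loss(y_pm, h))
    return GBDTModel(
        h0=h0, trees=trees, lr=lr, loss_curve=losses, n_features=X.shape[1]
    )


def predict_score(model: GBDTModel, X: np.ndarray) -> np.ndarray:
    """Additive score H(x) = h0 + lr * sum of reached leaf values."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if model.n_features is not None and X.shape[1] != model.n_features:
        raise ShapeError(
            f"model expects {model.n_features} features, got {X.shape[1]}"
        )
    h = np.full(X.shape[0], model.h0)
    for tree in model.trees:
        h += model.lr * tree.predict(X)
    return h


def predict_proba(model: GBDTModel, X: np.ndarray) -> np.ndarray:
    """P(positive) = sigmoid(2 H(x))."""
    h = np.clip(predict_score(model, X), -SCORE_CLIP, SCORE_CLIP)
    return 1.0 / (1.0 + np.exp(-2.0 * h))


def predict(model: GBDTModel, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    return (predict_proba(model, X) >= threshold).astype(int)


def model_to_json(model: GBDTModel, path: str | Path) -> None:
    payload = {
        "h0": model.h0,
        "lr": model.lr,
        "n_features": model.n_features,
        "loss_curve": model.loss_curve,
        "trees": [
            {
                "feature": t.feature,
                "threshold": t.threshold,
                "left": t.left,
                "right": t.right,
                "value": t.value,
            }
            for t in model.trees
        ],
    }
    Path(path).write_text(json.dumps(payload))


def model_from_json(path: str | Path) -> GBDTModel:
    payload = json.loads(Path(path).read_text())
    trees = [
        RegressionTree(
            feature=t["feature"],
            threshold=t["threshold"],
            left=t["left"],
            right=t["right"],
            value=t["value"],
        )
        for t in payload["trees"]
    ]
    return GBDTModel(
        h0=payload["h0"],
        trees=trees,
        lr=payload["lr"],
        loss_curve=payload["loss_curve"],
        n_features=payload["n_features"],
    )
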