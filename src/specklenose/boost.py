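"""Second-order gradient-boosted CART classifier, from scratch.

Additive tree ensemble trained on the regularized objective

    obj = sum_i l(y_i, yhat_i) + sum_trees [ gamma * T + (lambda/2) * sum_j w_j^2 ]

where each boosting round approximates the loss by its second-order
Taylor expansion in the per-instance gradient ``g_i`` and Hessian
``h_i``.  For a fixed tree structure the optimal leaf weight is

    w_j* = -G_j / (H_j + lambda)

with ``G_j``/``H_j`` the leaf sums of gradients/Hessians, and the
optimized objective of a partition (the "structure score") is

    obj* = -1/2 * sum_j G_j^2 / (H_j + lambda) + gamma * T.

Splits are found by exact greedy enumeration of every (feature,
threshold) candidate, scoring each by the structure-score reduction.
Multi-class training fits one regression tree per class per round on
the softmax gradients (g = p - 1{y=c}, h = p(1-p)).

No subsampling, histogram binning or missing-value routing: exact
greedy only, so split decisions can be checked against brute-force
enumeration.  Deterministic: ties in gain break toward the lowest
feature index, then the lowest threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GBTParams",
    "GradHess",
    "Tree",
    "Ensemble",
    "DegenerateLeafError",
    "softmax_grad_hess",
    "leaf_weight",
    "structure_score",
    "split_gain",
    "grow_tree",
    "fit",
    "fit_arrays",
    "predict_proba",
    "predict_labels",
]


class DegenerateLeafError(ValueError):
    """Raised when a leaf has no instances or non-positive H + lambda."""


@dataclass(frozen=True)
class GBTParams:
    """Boosting hyperparameters.

    eta
        Shrinkage applied to each tree's leaf weights, in (0, 1].
    max_depth
        Maximum tree depth (root = depth 0 split).
    gamma
        Complexity penalty per leaf; a split must improve the structure
        score by more than ``gamma`` to be kept.
    lambda_reg
        L2 penalty on leaf weights.
    n_rounds
        Number of boosting rounds (trees per class).
    min_child_hessian
        Minimum summed Hessian per child; guards near-empty leaves.
    """

    eta: float = 0.1
    max_depth: int = 4
    gamma: float = 0.0
    lambda_reg: float = 1.0
    n_rounds: int = 100
    min_child_hessian: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.eta <= 1:
            raise ValueError("eta must lie in (0, 1]")
        if self.gamma < 0 or self.lambda_reg < 0:
            raise ValueError("gamma and lambda_reg must be >= 0")
        if self.max_depth < 1 or self.n_rounds < 1:
            raise ValueError("max_depth and n_rounds must be >= 1")


@dataclass(frozen=True)
class GradHess:
    """Per-instance (optionally per-class) gradients and Hessians."""

    g: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        if self.g.shape != self.h.shape:
            raise ValueError("g and h must share a shape")


def softmax_grad_hess(labels: np.ndarray, raw_scores: np.ndarray) -> GradHess:
    """Gradients/Hessians of the softmax log-loss at the given raw scores.

    For class c: ``g = p_c - 1{y=c}`` and ``h = p_c (1 - p_c)`` with
    ``p = softmax(raw_scores)`` (stabilized by max subtraction).
    """
    raw_scores = np.asarray(raw_scores, dtype=np.float64)
    if not np.all(np.isfinite(raw_scores)):
        raise FloatingPointError("raw scores contain non-finite values")
    n, n_classes = raw_scores.shape
    labels = np.asarray(labels, dtype=np.int64)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels must lie in [0, n_classes)")
    z = raw_scores - raw_scores.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    g = p.copy()
    g[np.arange(n), labels] -= 1.0
    h = p * (1.0 - p)
    return GradHess(g=g, h=h)


def leaf_weight(G: float, H: float, lambda_reg: float) -> float:
    """Optimal leaf weight ``-G / (H + lambda)``."""
    denom = H + lambda_reg
    if denom <= 0:
        raise DegenerateLeafError(f"H + lambda = {denom} is not positive")
    return -G / denom


def structure_score(
    leaf_ids: np.ndarray,
    g: np.ndarray,
    h: np.ndarray,
    lambda_reg: float,
    gamma: float,
    n_leaves: int | None = None,
) -> float:
    """Optimized objective ``-1/2 sum_j G_j^2/(H_j+lambda) + gamma*T``.

    ``leaf_ids`` assigns every instance to a leaf; passing ``n_leaves``
    asserts the intended partition size, so a leaf left empty by the
    assignment raises instead of being silently dropped.
    """
    leaf_ids = np.asarray(leaf_ids)
    g = np.asarray(g, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    uniq = np.unique(leaf_ids)
    if n_leaves is not None and len(uniq) != n_leaves:
        raise DegenerateLeafError(
            f"partition declares {n_leaves} leaves but only {len(uniq)} are populated"
        )
    total = 0.0
    for leaf in uniq:
        mask = leaf_ids == leaf
        if not mask.any():
            raise DegenerateLeafError(f"leaf {leaf} is empty")
        G = g[mask].sum()
        H = h[mask].sum()
        if H + lambda_reg <= 0:
            raise DegenerateLeafError("leaf with non-positive H + lambda")
        total -= 0.5 * G**2 / (H + lambda_reg)
    return total + gamma * len(uniq)


def split_gain(
    GL: float, HL: float, GR: float, HR: float, lambda_reg: float, gamma: float
) -> float:
    """Structure-score reduction of splitting a parent into (L, R)."""
    lam = lambda_reg
    return 0.5 * (
        GL**2 / (HL + lam) + GR**2 / (HR + lam) - (GL + GR) ** 2 / (HL + HR + lam)
    ) - gamma


@dataclass
class Tree:
    """Regression tree as parallel node arrays.

    ``feature[i] < 0`` marks a leaf with weight ``value[i]``; internal
    nodes route ``x[feature] < threshold`` to ``left`` else ``right``.
    """

    feature: list[int] = dc_field(default_factory=list)
    threshold: list[float] = dc_field(default_factory=list)
    left: list[int] = dc_field(default_factory=list)
    right: list[int] = dc_field(default_factory=list)
    value: list[float] = dc_field(default_factory=list)
    leaf_stats: list[tuple[float, float] | None] = dc_field(default_factory=list)

    def _add_node(self) -> int:
        for arr, fill in (
            (self.feature, -1), (self.threshold, 0.0), (self.left, -1),
            (self.right, -1), (self.value, 0.0), (self.leaf_stats, None),
        ):
            arr.append(fill)
        return len(self.feature) - 1

    @property
    def n_leaves(self) -> int:
        return sum(1 for f in self.feature if f < 0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        out = np.empty(X.shape[0])
        for i, row in enumerate(X):
            node = 0
            while self.feature[node] >= 0:
                node = self.left[node] if row[self.feature[node]] < self.threshold[node] else self.right[node]
            out[i] = self.value[node]
        return out

    def leaf_weights(self) -> list[tuple[float, float, float]]:
        """(G, H, stored weight) for every leaf, for auditing."""
        return [
            (self.leaf_stats[i][0], self.leaf_stats[i][1], self.value[i])
            for i in range(len(self.feature))
            if self.feature[i] < 0
        ]


def _best_split(
    X: np.ndarray, g: np.ndarray, h: np.ndarray, idx: np.ndarray, params: GBTParams
) -> tuple[float, int, float] | None:
    """Exact greedy search over all (feature, midpoint-threshold) pairs.

    Returns (gain, feature, threshold) of the best admissible split, or
    None.  Ties break toward the lowest feature index then the lowest
    threshold (first strict improvement wins while scanning ascending).
    """
    Gp = g[idx].sum()
    Hp = h[idx].sum()
    lam = params.lambda_reg
    parent_term = Gp**2 / (Hp + lam)
    best: tuple[float, int, float] | None = None
    for j in range(X.shape[1]):
        xj = X[idx, j]
        order = np.argsort(xj, kind="stable")
        xs = xj[order]
        gs = g[idx][order]
        hs = h[idx][order]
        Gl = np.cumsum(gs)[:-1]
        Hl = np.cumsum(hs)[:-1]
        boundary = xs[1:] != xs[:-1]
        if not boundary.any():
            continue
        Gr = Gp - Gl
        Hr = Hp - Hl
        ok = boundary & (Hl >= params.min_child_hessian) & (Hr >= params.min_child_hessian)
        if not ok.any():
            continue
        gains = 0.5 * (Gl**2 / (Hl + lam) + Gr**2 / (Hr + lam) - parent_term) - params.gamma
        gains[~ok] = -np.inf
        k = int(np.argmax(gains))
        gain = float(gains[k])
        if gain <= 0:
            continue
        threshold = float(0.5 * (xs[k] + xs[k + 1]))
        if best is None or gain > best[0] + 1e-12:
            best = (gain, j, threshold)
    return best


def grow_tree(
    grad_hess: GradHess | tuple[np.ndarray, np.ndarray],
    X: np.ndarray,
    params: GBTParams,
) -> Tree:
    """Grow one regression tree on per-instance (g, h) by exact greedy.

    Depth-first: each node takes the (feature, threshold) maximizing the
    structure-score gain; growth stops at ``max_depth``, non-positive
    gain, or a child Hessian below ``min_child_hessian``.  Leaves carry
    the optimal weight ``-G/(H+lambda)``.
    """
    if isinstance(grad_hess, GradHess):
        g, h = grad_hess.g, grad_hess.h
    else:
        g, h = grad_hess
    g = np.asarray(g, dtype=np.float64)
    h = np.asarray(h, dtype=np.float64)
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] < 1:
        raise ValueError("grow_tree needs at least one instance")
    tree = Tree()

    def build(idx: np.ndarray, depth: int) -> int:
        node = tree._add_node()
        split = _best_split(X, g, h, idx, params) if depth < params.max_depth else None
        if split is None:
            G = float(g[idx].sum())
            H = float(h[idx].sum())
            tree.feature[node] = -1
            tree.value[node] = leaf_weight(G, H, params.lambda_reg)
            tree.leaf_stats[node] = (G, H)
            return node
        _, feat, thr = split
        mask = X[idx, feat] < thr
        tree.feature[node] = feat
        tree.threshold[node] = thr
        tree.left[node] = build(idx[mask], depth + 1)
        tree.right[node] = build(idx[~mask], depth + 1)
        return node

    build(np.arange(X.shape[0]), 0)
    return tree


@dataclass
class Ensemble:
    """Additive tree ensemble: ``trees[round][class]`` plus metadata.

    Raw score for class c is ``base_score + eta * sum_t trees[t][c](x)``;
    class probabilities are the softmax of the raw scores.
    """

    trees: list[list[Tree]]
    class_order: list[str]
    params: GBTParams
    feature_names: list[str]
    base_score: float = 0.0
    train_log: list[dict] = dc_field(default_factory=list)

    @property
    def n_classes(self) -> int:
        return len(self.class_order)

    def raw_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        scores = np.full((X.shape[0], self.n_classes), self.base_score)
        for round_trees in self.trees:
            for c, tree in enumerate(round_trees):
                scores[:, c] += self.params.eta * tree.predict(X)
        return scores

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        def tree_doc(t: Tree) -> dict:
            return dict(
                feature=t.feature, threshold=t.threshold, left=t.left,
                right=t.right, value=t.value,
                leaf_stats=[list(s) if s else None for s in t.leaf_stats],
            )

        doc = dict(
            format="specklenose-gbt-1",
            params=self.params.__dict__,
            class_order=self.class_order,
            feature_names=self.feature_names,
            base_score=self.base_score,
            trees=[[tree_doc(t) for t in row] for row in self.trees],
            train_log=self.train_log,
        )
        return json.dumps(doc)

    def save(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "Ensemble":
        doc = json.loads(text)
        trees = [
            [
                Tree(
                    feature=td["feature"], threshold=td["threshold"],
                    left=td["left"], right=td["right"], value=td["value"],
                    leaf_stats=[tuple(s) if s else None for s in td["leaf_stats"]],
                )
                for td in row
            ]
            for row in doc["trees"]
        ]
        return cls(
            trees=trees, class_order=doc["class_order"],
            params=GBTParams(**doc["params"]),
            feature_names=doc["feature_names"],
            base_score=doc["base_score"], train_log=doc["train_log"],
        )

    @classmethod
    def load(cls, path: str | Path) -> "Ensemble":
        return cls.from_json(Path(path).read_text())


def _log_loss(labels: np.ndarray, raw: np.ndarray) -> float:
    z = raw - raw.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    return float(-logp[np.arange(len(labels)), labels].sum())


def _penalty(trees: Sequence[Sequence[Tree]], params: GBTParams) -> float:
    total = 0.0
    for row in trees:
        for t in row:
            weights = np.array([w for _, _, w in t.leaf_weights()])
            total += params.gamma * t.n_leaves
            total += 0.5 * params.lambda_reg * float(((params.eta * weights) ** 2).sum())
    return total


def fit_arrays(
    X: np.ndarray,
    labels: np.ndarray,
    params: GBTParams,
    class_order: Sequence[str] | None = None,
    feature_names: Sequence[str] | None = None,
) -> Ensemble:
    """Train on a numeric matrix with integer-encoded labels.

    Per round, one tree per class is grown on the softmax gradients and
    the raw scores advance by ``eta`` times the tree output.  The log
    records the training log-loss and the regularized objective
    (log-loss plus the per-leaf and L2 weight penalties) per round.
    """
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    n_classes = len(class_order) if class_order is not None else int(labels.max()) + 1
    ens = Ensemble(
        trees=[],
        class_order=list(class_order) if class_order is not None
        else [str(c) for c in range(n_classes)],
        params=params,
        feature_names=list(feature_names) if feature_names is not None
        else [f"f{j}" for j in range(X.shape[1])],
    )
    raw = np.zeros((X.shape[0], n_classes))
    for round_idx in range(params.n_rounds):
        gh = softmax_grad_hess(labels, raw)
        round_trees: list[Tree] = []
        for c in range(n_classes):
            tree = grow_tree((gh.g[:, c], gh.h[:, c]), X, params)
            raw[:, c] += params.eta * tree.predict(X)
            round_trees.append(tree)
        ens.trees.append(round_trees)
        loss = _log_loss(labels, raw)
        ens.train_log.append(
            dict(round=round_idx, log_loss=loss,
                 objective=loss + _penalty(ens.trees, params))
        )
    return ens


def fit(
    table: pd.DataFrame,
    params: GBTParams,
    feature_cols: Sequence[str] | None = None,
    label_col: str = "smell",
) -> Ensemble:
    """Train from a labelled feature table (rows = chunks)."""
    from .features import FEATURE_NAMES

    feature_cols = list(feature_cols) if feature_cols is not None else [
        c for c in FEATURE_NAMES if c in table.columns
    ]
    if not feature_cols:
        raise ValueError("no feature columns found in table")
    class_order = sorted(table[label_col].unique().tolist())
    codes = table[label_col].map({c: i for i, c in enumerate(class_order)}).to_numpy()
    return fit_arrays(
        table[feature_cols].to_numpy(), codes, params,
        class_order=class_order, feature_names=feature_cols,
    )


def predict_proba(ensemble: Ensemble, X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Softmax class probabilities (rows sum to 1)."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in ensemble.feature_names if c not in X.columns]
        if missing:
            raise ValueError(f"input lacks feature columns: {missing[:5]}")
        X = X[ensemble.feature_names].to_numpy()
    raw = ensemble.raw_scores(X)
    z = raw - raw.max(axis=1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=1, keepdims=True)
    return p


def predict_labels(ensemble: Ensemble, X: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Most probable class label per row."""
    p = predict_proba(ensemble, X)
    return np.array([ensemble.class_order[i] for i in p.argmax(axis=1)])
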