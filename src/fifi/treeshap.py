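"""Path-dependent TreeSHAP for scikit-learn decision trees and forests.

Computes exact Shapley values for tree-ensemble predictions under the
path-dependent feature perturbation: when a feature is "absent", the
tree is descended into both children weighted by their training cover,
so the background distribution is the one the tree itself recorded.
The algorithm keeps, for every node on the current root-to-leaf path, a
summary of the proportion of feature subsets of each cardinality that
flow hot (feature present) and cold (feature absent), giving an O(L·D²)
cost per sample per tree instead of an exponential subset enumeration.

Local accuracy holds exactly: for each sample, the Shapley values sum
to the model output minus the cover-weighted expected leaf value.

For classifiers the explained output is the probability of the
positive class (label 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor


@dataclass
class _Tree:
    """Flat view of one fitted sklearn tree with scalar leaf values."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    cover: np.ndarray  # weighted training samples per node
    value: np.ndarray  # scalar output per node

    @property
    def expected_value(self) -> float:
        return float(self.value[0])


def _extract_tree(estimator, positive_class_index: int | None) -> _Tree:
    t = estimator.tree_
    raw = t.value[:, 0, :]
    if positive_class_index is not None:
        totals = raw.sum(axis=1)
        value = raw[:, positive_class_index] / np.where(totals > 0, totals, 1.0)
    else:
        value = raw[:, 0]
    # internal node value = cover-weighted mean of its leaves, which
    # sklearn already stores; root value is the tree's expected output
    return _Tree(
        children_left=t.children_left,
        children_right=t.children_right,
        feature=t.feature,
        threshold=t.threshold,
        cover=t.weighted_n_node_samples,
        value=value.astype(float),
    )


def _decompose(model) -> tuple[list[_Tree], float]:
    """Split a supported model into trees with equal output weights."""
    if isinstance(model, (DecisionTreeRegressor, DecisionTreeClassifier)):
        cls_idx = _positive_index(model) if isinstance(model, DecisionTreeClassifier) else None
        trees = [_extract_tree(model, cls_idx)]
    elif isinstance(model, (RandomForestRegressor, RandomForestClassifier)):
        cls_idx = _positive_index(model) if isinstance(model, RandomForestClassifier) else None
        trees = [_extract_tree(e, cls_idx) for e in model.estimators_]
    else:
        raise TypeError(
            f"tree SHAP requires a decision tree or random forest, got {type(model).__name__}"
        )
    weight = 1.0 / len(trees)
    return trees, weight


def _positive_index(model) -> int:
    classes = list(model.classes_)
    if 1 in classes:
        return classes.index(1)
    return len(classes) - 1


# One path element per node on the current path:
# d — feature that split there, z — cold (absent) flow fraction,
# o — hot (present) flow fraction, w — subset-proportion weights.
def _extend(path: list[list[float]], pz: float, po: float, pi: int) -> None:
    path.append([pi, pz, po, 1.0 if not path else 0.0])
    l = len(path) - 1
    for i in range(l - 1, -1, -1):
        path[i + 1][3] += po * path[i][3] * (i + 1) / (l + 1)
        path[i][3] = pz * path[i][3] * (l - i) / (l + 1)


def _unwind(path: list[list[float]], i: int) -> None:
    l = len(path) - 1
    o, z = path[i][2], path[i][1]
    n = path[l][3]
    for j in range(l - 1, -1, -1):
        if o != 0:
            t = path[j][3]
            path[j][3] = n * (l + 1) / ((j + 1) * o)
            n = t - path[j][3] * z * (l - j) / (l + 1)
        else:
            path[j][3] = path[j][3] * (l + 1) / (z * (l - j))
    for j in range(i, l):
        path[j][0], path[j][1], path[j][2] = path[j + 1][0], path[j + 1][1], path[j + 1][2]
    path.pop()


def _unwound_sum(path: list[list[float]], i: int) -> float:
    l = len(path) - 1
    o, z = path[i][2], path[i][1]
    total = 0.0
    if o != 0:
        n = path[l][3]
        for j in range(l - 1, -1, -1):
            t = n / ((j + 1) * o)
            total += t
            n = path[j][3] - t * z * (l - j)
    else:
        for j in range(l - 1, -1, -1):
            total += path[j][3] / (z * (l - j))
    return total * (l + 1)


def _tree_shap_row(tree: _Tree, x: np.ndarray, phi: np.ndarray) -> None:
    def recurse(node: int, path: list[list[float]], pz: float, po: float, pi: int) -> None:
        path = [list(e) for e in path]
        _extend(path, pz, po, pi)
        left = tree.children_left[node]
        if left < 0:  # leaf
            for i in range(1, len(path)):
                w = _unwound_sum(path, i)
                el = path[i]
                phi[int(el[0])] += w * (el[2] - el[1]) * tree.value[node]
            return
        right = tree.children_right[node]
        d = int(tree.feature[node])
        hot, cold = (left, right) if x[d] <= tree.threshold[node] else (right, left)
        iz, io = 1.0, 1.0
        k = next((i for i in range(1, len(path)) if path[i][0] == d), None)
        if k is not None:
            iz, io = path[k][1], path[k][2]
            _unwind(path, k)
        cover = tree.cover[node]
        recurse(hot, path, iz * tree.cover[hot] / cover, io, d)
        recurse(cold, path, iz * tree.cover[cold] / cover, 0.0, d)

    recurse(0, [], 1.0, 1.0, -1)


def shap_values(model, X) -> tuple[np.ndarray, float]:
    """Per-feature Shapley values for every row of ``X``.

    Returns ``(phi, expected_value)`` where ``phi`` has one row per
    sample and one column per feature, and for every row
    ``phi.sum() + expected_value == model output`` (probability of the
    positive class for classifiers) up to floating-point error.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    trees, weight = _decompose(model)
    phi = np.zeros((X.shape[0], X.shape[1]))
    for tree in trees:
        for row_idx in range(X.shape[0]):
            row_phi = np.zeros(X.shape[1])
            _tree_shap_row(tree, X[row_idx], row_phi)
            phi[row_idx] += weight * row_phi
    expected = float(sum(weight * t.expected_value for t in trees))
    return phi, expected


def expected_output(model, x: Sequence[float]) -> float:
    """The model output that SHAP values decompose (probability of the
    positive class for classifiers, prediction for regressors)."""
    x = np.asarray(x, dtype=float)[None, :]
    if hasattr(model, "predict_proba"):
        col = _positive_index(model)
        return float(model.predict_proba(x)[0, col])
    return float(model.predict(x)[0])
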