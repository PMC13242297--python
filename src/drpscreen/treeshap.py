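"""Exact SHAP values for scikit-learn tree ensembles.

Implements the path-dependent polynomial-time algorithm for Shapley additive
explanations of tree models (Lundberg et al., "Consistent Individualized
Feature Attribution for Tree Ensembles").  Conditional expectations over
feature subsets are estimated by the tree's own training cover: when a split
feature is "absent", both branches are followed weighted by their training
sample counts.  This satisfies local accuracy exactly:

    sum_j phi_j(x) + expected_value == model.predict(x)

for every x, which the test suite asserts, alongside agreement with a
brute-force Shapley enumeration on small trees.

Supported models: DecisionTreeRegressor, RandomForestRegressor (mean of
per-tree attributions) and GradientBoostingRegressor (learning-rate-scaled
sum plus the constant initial estimate).
"""

from __future__ import annotations

import sys

import numpy as np

VARIANT = "tree_path_dependent"


class _PathElement:
    __slots__ = ("d", "z", "o", "w")

    def __init__(self, d, z, o, w):
        self.d = d  # feature index of the split that created this element
        self.z = z  # fraction of "cold" (absent-feature) paths that flow through
        self.o = o  # fraction of "hot" (present-feature) paths that flow through
        self.w = w  # proportion of permutation subsets of this size

    def copy(self):
        return _PathElement(self.d, self.z, self.o, self.w)


def _extend(m, pz, po, pi):
    l = len(m)
    m = [e.copy() for e in m]
    m.append(_PathElement(pi, pz, po, 1.0 if l == 0 else 0.0))
    for i in range(l - 1, -1, -1):
        m[i + 1].w += po * m[i].w * (i + 1) / (l + 1)
        m[i].w = pz * m[i].w * (l - i) / (l + 1)
    return m


def _unwind(m, i):
    l = len(m) - 1
    o_i, z_i = m[i].o, m[i].z
    n = m[l].w
    m = [e.copy() for e in m]
    for j in range(l - 1, -1, -1):
        if o_i != 0:
            t = m[j].w
            m[j].w = n * (l + 1) / ((j + 1) * o_i)
            n = t - m[j].w * z_i * (l - j) / (l + 1)
        else:
            m[j].w = m[j].w * (l + 1) / (z_i * (l - j))
    for j in range(i, l):
        m[j].d, m[j].z, m[j].o = m[j + 1].d, m[j + 1].z, m[j + 1].o
    return m[:-1]


def _unwound_sum(m, i):
    l = len(m) - 1
    o_i, z_i = m[i].o, m[i].z
    n = m[l].w
    total = 0.0
    for j in range(l - 1, -1, -1):
        if o_i != 0:
            t = n * (l + 1) / ((j + 1) * o_i)
            total += t
            n = m[j].w - t * z_i * (l - j) / (l + 1)
        else:
            total += m[j].w * (l + 1) / (z_i * (l - j))
    return total


def _tree_shap_single(tree, x, phi, scale=1.0):
    """Accumulate SHAP values of one fitted sklearn tree into ``phi``."""
    left = tree.children_left
    right = tree.children_right
    feature = tree.feature
    threshold = tree.threshold
    value = tree.value[:, 0, 0]
    cover = tree.weighted_n_node_samples

    def recurse(j, m, pz, po, pi):
        m = _extend(m, pz, po, pi)
        if left[j] < 0:  # leaf
            leaf = value[j] * scale
            for i in range(1, len(m)):
                phi[m[i].d] += _unwound_sum(m, i) * (m[i].o - m[i].z) * leaf
            return
        f = feature[j]
        if x[f] <= threshold[j]:
            hot, cold = left[j], right[j]
        else:
            hot, cold = right[j], left[j]
        iz = io = 1.0
        k = next((i for i in range(1, len(m)) if m[i].d == f), 0)
        if k:
            iz, io = m[k].z, m[k].o
            m = _unwind(m, k)
        recurse(hot, m, iz * cover[hot] / cover[j], io, f)
        recurse(cold, m, iz * cover[cold] / cover[j], 0.0, f)

    recurse(0, [], 1.0, 1.0, -1)


def _tree_expected(tree, scale=1.0):
    # the root value of a regression tree is the cover-weighted mean leaf value
    return float(tree.value[0, 0, 0]) * scale


def _ensemble_trees(model):
    """Yield (tree_, scale, combine) pieces plus the base offset of a model."""
    from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
    from sklearn.tree import DecisionTreeRegressor

    if isinstance(model, DecisionTreeRegressor):
        return [(model.tree_, 1.0)], 0.0
    if isinstance(model, RandomForestRegressor):
        n = len(model.estimators_)
        return [(e.tree_, 1.0 / n) for e in model.estimators_], 0.0
    if isinstance(model, GradientBoostingRegressor):
        lr = model.learning_rate
        trees = [(e.tree_, lr) for e in model.estimators_[:, 0]]
        base = float(model.init_.predict(np.zeros((1, model.n_features_in_)))[0])
        return trees, base
    raise TypeError(f"unsupported model type {type(model).__name__}")


def shap_values(model, X: np.ndarray) -> tuple[np.ndarray, float]:
    """SHAP attribution matrix and expected value for a tree model.

    Returns ``(phi, expected_value)`` with ``phi`` of shape (n_samples,
    n_features); rows satisfy ``phi.sum(1) + expected_value ==
    model.predict(X)`` to floating precision.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    trees, base = _ensemble_trees(model)
    n_features = X.shape[1]
    phi = np.zeros((X.shape[0], n_features))
    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10000))
    try:
        for tree, scale in trees:
            for r in range(X.shape[0]):
                _tree_shap_single(tree, X[r], phi[r], scale)
    finally:
        sys.setrecursionlimit(old_limit)
    expected = base + sum(_tree_expected(t, s) for t, s in trees)
    return phi, float(expected)
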