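"""A C4.5-style decision tree for binary features.

Splits maximize the gain ratio (information gain normalized by the split
entropy), considering only attributes whose gain is at least the average gain
of all candidate attributes, and the grown tree is simplified by error-based
pessimistic pruning with the classic confidence factor CF = 0.25: a subtree is
replaced by a leaf when the leaf's upper-confidence error estimate does not
exceed the subtree's.

Features are expected to be 0/1 (the ROI states produced upstream); the class
is binary. The estimator follows the scikit-learn fit/predict convention so it
can stand next to library classifiers in the cross-validation grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import betaincinv, xlogy

__all__ = ["C45Tree"]


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(-xlogy(p, p).sum() / np.log(2))


def _upper_error(errors: float, n: float, cf: float = 0.25) -> float:
    """C4.5 pessimistic upper bound on the true error rate at a node.

    Solves P(X <= E | N, p) = CF for p via the regularized incomplete beta
    inverse; returns the expected error count n * p.
    """
    if n == 0:
        return 0.0
    e = min(errors, n)
    if e >= n:
        return float(n)
    # P(Bin(N, p) <= E) = I_{1-p}(N-E, E+1) = CF  =>  p = 1 - I^{-1}(CF; N-E, E+1)
    p = 1.0 - betaincinv(n - e, e + 1, cf)
    return float(n * p)


@dataclass
class _Node:
    majority: int
    counts: np.ndarray  # class counts at the node
    feature: int | None = None
    children: dict[int, "_Node"] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


class C45Tree:
    """Gain-ratio decision tree with error-based pruning for binary data."""

    def __init__(self, cf: float = 0.25, min_split: int = 2, prune: bool = True):
        self.cf = cf
        self.min_split = min_split
        self.prune = prune

    def fit(self, X, y):
        X = np.asarray(X, dtype=int)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        self.classes_, y_enc = np.unique(y, return_inverse=True)
        self.n_classes_ = len(self.classes_)
        self.root_ = self._grow(X, y_enc, set(range(X.shape[1])))
        if self.prune:
            self._prune(self.root_, X, y_enc)
        return self

    # -- growing ---------------------------------------------------------
    def _grow(self, X: np.ndarray, y: np.ndarray, attrs: set[int]) -> _Node:
        counts = np.bincount(y, minlength=self.n_classes_)
        node = _Node(majority=int(counts.argmax()), counts=counts)
        n = len(y)
        if n < self.min_split or (counts > 0).sum() <= 1 or not attrs:
            return node
        base = _entropy(counts)
        gains, ratios = {}, {}
        for a in sorted(attrs):
            col = X[:, a]
            info = split_info = 0.0
            for v in (0, 1):
                sel = col == v
                nv = sel.sum()
                if nv == 0:
                    continue
                info += nv / n * _entropy(np.bincount(y[sel], minlength=self.n_classes_))
                split_info -= nv / n * np.log2(nv / n)
            gain = base - info
            if split_info > 0 and gain > 1e-12:
                gains[a] = gain
                ratios[a] = gain / split_info
        if not gains:
            return node
        avg_gain = np.mean(list(gains.values()))
        eligible = [a for a, g in gains.items() if g >= avg_gain - 1e-12]
        best = max(eligible, key=lambda a: (ratios[a], -a))
        node.feature = best
        for v in (0, 1):
            sel = X[:, best] == v
            if sel.sum() == 0:
                node.children[v] = _Node(majority=node.majority, counts=np.zeros_like(counts))
            else:
                node.children[v] = self._grow(X[sel], y[sel], attrs - {best})
        return node

    # -- pruning ---------------------------------------------------------
    def _subtree_error(self, node: _Node) -> float:
        if node.is_leaf:
            n = node.counts.sum()
            return _upper_error(n - node.counts.max(initial=0), n, self.cf)
        return sum(self._subtree_error(ch) for ch in node.children.values())

    def _prune(self, node: _Node, X: np.ndarray, y: np.ndarray) -> None:
        if node.is_leaf:
            return
        for v, child in node.children.items():
            sel = X[:, node.feature] == v
            self._prune(child, X[sel], y[sel])
        n = node.counts.sum()
        leaf_err = _upper_error(n - node.counts.max(initial=0), n, self.cf)
        if leaf_err <= self._subtree_error(node) + 1e-12:
            node.feature = None
            node.children = {}

    # -- prediction ------------------------------------------------------
    def _predict_one(self, x: np.ndarray) -> int:
        node = self.root_
        while not node.is_leaf:
            child = node.children.get(int(x[node.feature]))
            if child is None or child.counts.sum() == 0:
                return node.majority
            node = child
        return node.majority

    def predict(self, X):
        X = np.asarray(X, dtype=int)
        return self.classes_[[self._predict_one(row) for row in X]]

    def get_params(self, deep=True):
        return {"cf": self.cf, "min_split": self.min_split, "prune": self.prune}

    def set_params(self, **kw):
        for k, v in kw.items():
            setattr(self, k, v)
        return self
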