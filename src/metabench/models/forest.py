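"""Random forest of CART trees with the study's fixed ensemble settings.

Fixed at 100 trees, sqrt(M) candidate features per split, and a minimum of
two samples to split; the tunable hyperparameters are the maximum tree depth
and the minimum fraction of training samples each leaf must hold.
"""

from __future__ import annotations

import math

import numpy as np
from sklearn.ensemble import RandomForestClassifier

__all__ = ["RandomForest"]


class RandomForest:
    def __init__(
        self,
        max_depth: int,
        min_leaf_fraction: float,
        seed: int = 0,
        n_trees: int = 100,
    ):
        if int(max_depth) != max_depth or max_depth < 1:
            raise ValueError("max_depth must be a positive integer")
        if not 0.0 < min_leaf_fraction <= 0.5:
            raise ValueError("min_leaf_fraction must lie in (0, 0.5]")
        self.max_depth = int(max_depth)
        self.min_leaf_fraction = float(min_leaf_fraction)
        self.seed = int(seed)
        self.n_trees = int(n_trees)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        if len(np.unique(y)) < 2:
            raise ValueError("y_train contains a single class; cannot fit a classifier")
        # float min_samples_leaf means ceil(fraction * n) in sklearn's CART
        self._forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            criterion="gini",
            max_depth=self.max_depth,
            min_samples_leaf=self.min_leaf_fraction,
            min_samples_split=2,
            max_features="sqrt",
            bootstrap=True,
            random_state=self.seed,
            n_jobs=1,
        )
        self._forest.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Fraction of trees voting for the positive class."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return self._forest.predict_proba(X)[:, 1]

    # structural introspection used by diagnostics and tests
    def tree_depths(self) -> list[int]:
        return [est.tree_.max_depth for est in self._forest.estimators_]

    def min_leaf_counts(self) -> list[int]:
        counts = []
        for est in self._forest.estimators_:
            t = est.tree_
            leaves = t.children_left == -1
            counts.append(int(t.n_node_samples[leaves].min()))
        return counts

    def min_samples_leaf_resolved(self, n_train: int) -> int:
        return max(1, math.ceil(self.min_leaf_fraction * n_train))
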