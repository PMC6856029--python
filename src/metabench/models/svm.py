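"""Support vector machines with linear and Gaussian RBF kernels.

The RBF kernel follows the standard convention ``K = exp(-gamma * ||x-y||^2)``.
ROC scores are the raw signed margin distances from ``decision_function``,
never thresholded labels, so that a full ROC curve can be traced.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf_kernel
from sklearn.svm import SVC

__all__ = ["rbf_kernel_matrix", "LinearSVM", "RBFSVM"]


def rbf_kernel_matrix(A: np.ndarray, B: np.ndarray, gamma: float) -> np.ndarray:
    """Gaussian kernel matrix ``K[i, j] = exp(-gamma * ||A_i - B_j||^2)``.

    Entries lie in (0, 1] with K(x, x) = 1; the matrix is symmetric when the
    two inputs coincide.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("A and B must share the feature dimension")
    return _sk_rbf_kernel(A, B, gamma=gamma)


# hard bound on libsvm SMO iterations: with a large C on inseparable data the
# solver can otherwise spin almost indefinitely for a negligible margin change
_MAX_ITER = 50_000


class _BaseSVM:
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int).ravel()
        if len(np.unique(y)) < 2:
            raise ValueError("y_train contains a single class; cannot fit a classifier")
        self._svc.fit(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return self._svc.decision_function(X)


class LinearSVM(_BaseSVM):
    """Maximum-margin linear classifier trained with hinge loss.

    ``C`` trades margin width against training misclassification: large C
    approaches a hard margin, small C a wide soft margin.
    """

    def __init__(self, C: float):
        if C <= 0:
            raise ValueError("C must be positive")
        self.C = float(C)
        self._svc = SVC(kernel="linear", C=self.C, max_iter=_MAX_ITER)


class RBFSVM(_BaseSVM):
    """SVM with the Gaussian radial basis kernel (kernel-trick nonlinearity)."""

    def __init__(self, C: float, gamma: float):
        if C <= 0:
            raise ValueError("C must be positive")
        if gamma <= 0:
            raise ValueError("gamma must be positive")
        self.C = float(C)
        self.gamma = float(gamma)
        self._svc = SVC(kernel="rbf", C=self.C, gamma=self.gamma, max_iter=_MAX_ITER)
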