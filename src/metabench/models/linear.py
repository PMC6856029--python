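"""Projection-based linear classifiers: PLS-DA, PCR, and PCLR.

All three reduce to a single linear form in the original feature space:
``y* = b0 + x . beta`` (PLS-DA, PCR) or ``logit(p+) = b0 + x . beta`` (PCLR).
Scores are continuous, oriented so that higher means more likely positive;
the conventional decision threshold is 0.5.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit
from sklearn.linear_model import LogisticRegression

from .simpls import effective_rank, simpls

__all__ = ["pca_decompose", "PLSDA", "PCR", "PCLR"]

_PROB_EPS = 1e-12


def pca_decompose(X: np.ndarray, k: int):
    """PCA of a centred matrix via SVD.

    Returns
    -------
    scores : (N, k), loadings : (M, k) orthonormal, explained_variance : (k,)
        Explained variances are the squared singular values over ``N - 1``,
        in non-increasing order. ``X == scores @ loadings.T`` exactly when
        ``k`` equals the rank of ``X``.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(X.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if not 1 <= k <= rank:
        raise ValueError(f"k must lie in [1, rank(X)={rank}], got {k}")
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    explained = s[:k] ** 2 / (n - 1)
    return scores, loadings, explained


def _check_fit_inputs(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be 2-D with one row per element of y")
    if len(np.unique(y)) < 2:
        raise ValueError("y_train contains a single class; cannot fit a classifier")
    return X, y


class _LinearScorer:
    """Shared linear-form plumbing: centring, coefficients, score contract."""

    coef_: np.ndarray
    intercept_: float
    n_features_in_: int

    def _linear(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1] if X.ndim == 2 else '?'}"
            )
        return self.intercept_ + X @ self.coef_


class PLSDA(_LinearScorer):
    """Partial least squares discriminant analysis fitted with SIMPLS.

    The binary outcome is treated as a 0/1 response; after fitting, the model
    is exactly ``y* = b0 + x . beta`` and a sample is called positive when
    ``y* > 0.5``.
    """

    def __init__(self, n_latent: int):
        if int(n_latent) != n_latent or n_latent < 1:
            raise ValueError("n_latent must be a positive integer")
        self.n_latent = int(n_latent)

    def fit(self, X, y):
        X, y = _check_fit_inputs(X, y)
        self._x_mean = X.mean(axis=0)
        self._y_mean = y.mean()
        fit = simpls(X - self._x_mean, y - self._y_mean, self.n_latent)
        self.coef_ = fit.beta
        self.intercept_ = float(self._y_mean - self._x_mean @ fit.beta)
        self.x_scores_ = fit.scores
        self.x_weights_ = fit.weights
        self.x_loadings_ = fit.loadings
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X) -> np.ndarray:
        return self._linear(X)


class PCR(_LinearScorer):
    """Principal component regression: PCA scores feeding a least-squares fit."""

    def __init__(self, n_components: int):
        if int(n_components) != n_components or n_components < 1:
            raise ValueError("n_components must be a positive integer")
        self.n_components = int(n_components)

    def fit(self, X, y):
        X, y = _check_fit_inputs(X, y)
        self._x_mean = X.mean(axis=0)
        y_mean = y.mean()
        scores, loadings, self.explained_variance_ = pca_decompose(
            X - self._x_mean, self.n_components
        )
        b, *_ = np.linalg.lstsq(scores, y - y_mean, rcond=None)
        self.coef_ = loadings @ b
        self.intercept_ = float(y_mean - self._x_mean @ self.coef_)
        self.loadings_ = loadings
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X) -> np.ndarray:
        return self._linear(X)


class PCLR(_LinearScorer):
    """Principal component logistic regression.

    PCA scores feed an unpenalised logistic regression whose coefficients are
    estimated by maximum likelihood (iteratively reweighted least squares via
    the Newton-Cholesky solver, gradient tolerance 1e-8, at most 100
    iterations). Scores are class-1 probabilities in the open interval (0, 1).
    """

    def __init__(self, n_components: int):
        if int(n_components) != n_components or n_components < 1:
            raise ValueError("n_components must be a positive integer")
        self.n_components = int(n_components)

    def fit(self, X, y):
        X, y = _check_fit_inputs(X, y)
        self._x_mean = X.mean(axis=0)
        scores, loadings, _ = pca_decompose(X - self._x_mean, self.n_components)
        # C=inf: unpenalised maximum likelihood; newton-cholesky is IRLS
        lr = LogisticRegression(
            C=np.inf, solver="newton-cholesky", tol=1e-8, max_iter=100
        )
        lr.fit(scores, y.astype(int))
        self.coef_ = loadings @ lr.coef_[0]
        self.intercept_ = float(lr.intercept_[0] - self._x_mean @ self.coef_)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X) -> np.ndarray:
        p = expit(self._linear(X))
        return np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)


# re-export for convenience
effective_rank = effective_rank
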