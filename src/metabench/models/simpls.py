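"""SIMPLS partial least squares for a single response.

Computes PLS factors directly from the cross-product vector without deflating
X. For a centred ``X`` (N x M) and centred ``y``, the model after ``A``
components reduces to a single coefficient vector ``beta`` with
``X @ beta`` identical to the latent-space regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SimplsFit", "simpls", "effective_rank"]


@dataclass(frozen=True)
class SimplsFit:
    beta: np.ndarray       # (M,) regression vector in the original feature space
    scores: np.ndarray     # (N, A) orthonormal latent scores T
    weights: np.ndarray    # (M, A) projection weights R, so T = X @ R
    loadings: np.ndarray   # (M, A) X-loadings P
    y_loadings: np.ndarray  # (A,) y-loadings q


def effective_rank(X: np.ndarray) -> int:
    """Numerical rank of X via SVD with the standard tolerance."""
    s = np.linalg.svd(np.asarray(X, dtype=float), compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    tol = s[0] * max(X.shape) * np.finfo(float).eps
    return int((s > tol).sum())


def simpls(X: np.ndarray, y: np.ndarray, n_latent: int) -> SimplsFit:
    """Fit ``n_latent`` SIMPLS components on centred data.

    Raises
    ------
    ValueError
        If ``n_latent`` is not in ``[1, rank(X)]``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on the number of samples")
    rank = effective_rank(X)
    if not 1 <= n_latent <= rank:
        raise ValueError(f"n_latent must lie in [1, rank(X)={rank}], got {n_latent}")

    T = np.empty((n, n_latent))
    P = np.empty((m, n_latent))
    R = np.empty((m, n_latent))
    V = np.empty((m, n_latent))
    q = np.empty(n_latent)

    s = X.T @ y  # cross-product vector; deflated in feature space each round
    for a in range(n_latent):
        r = s.copy()
        t = X @ r
        t -= t.mean()
        norm_t = np.linalg.norm(t)
        if norm_t <= np.finfo(float).eps * n:
            raise ValueError(f"latent component {a + 1} is numerically null")
        t /= norm_t
        r /= norm_t
        p = X.T @ t
        q[a] = y @ t
        v = p.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ p)
        v /= np.linalg.norm(v)
        s -= v * (v @ s)
        T[:, a], P[:, a], R[:, a], V[:, a] = t, p, r, v

    beta = R @ q
    return SimplsFit(beta=beta, scores=T, weights=R, loadings=P, y_loadings=q)
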