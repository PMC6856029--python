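"""Evaluation statistics: coefficient of determination (R²/Q²), ROC, AUC.

The AUC reported everywhere in the package is the trapezoidal area under the
tie-grouped ROC curve, which is algebraically identical to the Mann-Whitney
concordance probability with ties counted one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["RocCurve", "coefficient_of_determination", "roc_curve", "auc", "auc_mann_whitney"]


@dataclass(frozen=True)
class RocCurve:
    """An ROC curve as ordered (FPR, TPR) points with decision thresholds."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def interpolate(self, fpr_grid: np.ndarray) -> np.ndarray:
        """Linearly interpolate the TPR onto a common FPR grid.

        The curve is anchored at (0, 0): the step function's value at an FPR
        of exactly zero is taken as zero (the usual convention when averaging
        or banding ROC curves), rather than the extreme-value TPR reached
        before the first false positive.
        """
        fpr_grid = np.asarray(fpr_grid, dtype=float)
        tpr = np.interp(fpr_grid, self.fpr, self.tpr)
        tpr[fpr_grid == 0.0] = 0.0
        return tpr

    @property
    def area(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("y must be coded {0,1}")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    return y.astype(int)


def coefficient_of_determination(y, y_star, center: float | None = None) -> float:
    """``1 - SS_res/SS_tot``: at most 1, unbounded below.

    ``center`` overrides the mean used in ``SS_tot``; the cross-validated Q²
    statistic passes the full-training-set mean here so that each repartition
    is referenced against the same null model.
    """
    y = np.asarray(y, dtype=float)
    y_star = np.asarray(y_star, dtype=float)
    if y.shape != y_star.shape or y.size < 2:
        raise ValueError("y and y_star must be equal-length vectors of size >= 2")
    mu = float(np.mean(y)) if center is None else float(center)
    ss_tot = float(np.sum((y - mu) ** 2))
    if ss_tot == 0.0:
        raise ValueError("coefficient of determination undefined for constant y")
    ss_res = float(np.sum((y - y_star) ** 2))
    return 1.0 - ss_res / ss_tot


def roc_curve(y, scores) -> RocCurve:
    """Tie-grouped ROC curve from (0,0) to (1,1), both coordinates non-decreasing."""
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr)


def auc(y, scores) -> float:
    """Area under the ROC curve (trapezoidal; ties contribute one half)."""
    return roc_curve(y, scores).area


def auc_mann_whitney(y, scores) -> float:
    """AUC as the rank-based Mann-Whitney concordance probability.

    An alternative route to the same number as :func:`auc`; kept as a public
    cross-check of the trapezoidal form.
    """
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    ranks = rankdata(scores)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))
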