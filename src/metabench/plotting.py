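"""Diagnostic figures: hyperparameter-selection planes and bootstrap ROC bands."""

from __future__ import annotations

import numpy as np

from .bootstrap import BootstrapEvaluation, TrainTestEvaluation
from .hyperopt import CVSurface, ParetoSelection


def plot_selection(surface: CVSurface, selection: ParetoSelection, ax=None):
    """Scatter the (performance, gap) plane with the Pareto front and knee.

    For a one-dimensional grid a companion panel shows the classic metric-vs-
    hyperparameter curves.
    """
    import matplotlib.pyplot as plt

    one_d = len(surface.grid.axes) == 1
    if ax is None:
        fig, axes = plt.subplots(1, 2 if one_d else 1, figsize=(10 if one_d else 5, 4))
        axes = np.atleast_1d(axes)
    else:
        axes = np.atleast_1d(ax)
        fig = axes[0].figure

    pts = np.asarray(selection.points)
    pane = axes[-1]
    pane.scatter(pts[:, 0], pts[:, 1], s=18, color="0.6", label="grid")
    front = pts[list(selection.front_indices)]
    pane.plot(front[:, 0], front[:, 1], "o-", color="tab:blue", label="Pareto front")
    cx, cy = pts[selection.chosen_index]
    pane.scatter([cx], [cy], s=90, facecolor="none", edgecolor="tab:red",
                 linewidth=2, label=f"chosen ({selection.rule})")
    pane.axhline(selection.fallback_line, ls=":", color="0.4")
    perf = "Q2" if selection.metric_basis == "R2Q2" else "AUC_CV"
    gap = "|R2-Q2|" if selection.metric_basis == "R2Q2" else "|AUC_full-AUC_CV|"
    pane.set_xlabel(perf)
    pane.set_ylabel(gap)
    pane.legend(fontsize=8)
    pane.set_title(surface.family)

    if one_d:
        name, values = surface.grid.axes[0]
        xs = [rec.params[name] for rec in surface.records]
        if selection.metric_basis == "R2Q2":
            full = [rec.r2 for rec in surface.records]
            cv = [rec.q2 for rec in surface.records]
            labels = ("R2", "Q2")
        else:
            full = [rec.auc_full for rec in surface.records]
            cv = [rec.auc_cv for rec in surface.records]
            labels = ("AUC_full", "AUC_CV")
        axes[0].plot(xs, full, "o-", label=labels[0])
        axes[0].plot(xs, cv, "s-", label=labels[1])
        chosen_x = surface.records[selection.chosen_index].params[name]
        axes[0].axvline(chosen_x, color="tab:red", ls="--")
        axes[0].set_xlabel(name)
        axes[0].legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_roc_bands(train_test: TrainTestEvaluation, boot: BootstrapEvaluation, ax=None):
    """Train/test ROC curves over the IB and OOB 95% bootstrap bands."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(5, 5))
    else:
        fig = ax.figure
    g = boot.fpr_grid
    ax.fill_between(g, *boot.ib_band, color="tab:green", alpha=0.2, label="IB 95% band")
    ax.fill_between(g, *boot.oob_band, color="tab:orange", alpha=0.25, label="OOB 95% band")
    ax.plot(train_test.roc_train.fpr, train_test.roc_train.tpr, color="tab:green",
            label=f"train (AUC={train_test.auc_train:.2f})")
    ax.plot(train_test.roc_test.fpr, train_test.roc_test.tpr, color="tab:orange",
            label=f"test (AUC={train_test.auc_test:.2f})")
    ax.plot([0, 1], [0, 1], ls=":", color="0.5")
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8, loc="lower right")
    fig.tight_layout()
    return fig
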