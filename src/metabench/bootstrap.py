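"""Final-model evaluation: train/test ROC and out-of-bag bootstrap bands.

After hyperparameter selection the model is judged twice:

* once on the held-out test set, with preprocessing statistics frozen on the
  training rows (``evaluate_train_test``);
* once by stratified bootstrap resampling of the complete dataset
  (``bootstrap_evaluate``): each of ``n_boot`` resamples draws N samples with
  replacement within class (the in-bag sample, IB, covering ~63.2% of unique
  samples), refits preprocessing and model on the IB rows, and scores both
  the IB multiset and the untouched out-of-bag (OOB) rows. The resulting
  ROC curves are interpolated onto a common false-positive-rate grid and
  summarised as pointwise 2.5/97.5 percentile bands with matching AUC
  intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import SplitIndices, TidyDataset, apply_preprocessing, fit_preprocessing
from .hyperopt import subseed
from .metrics import RocCurve, auc, roc_curve
from .models import ModelSpec, fit_model, predict_scores

logger = logging.getLogger("metabench")

__all__ = [
    "TrainTestEvaluation",
    "BootstrapEvaluation",
    "evaluate_train_test",
    "bootstrap_evaluate",
    "summarise_runs",
    "pairwise_auc_differences",
]


@dataclass(frozen=True)
class TrainTestEvaluation:
    spec: ModelSpec
    auc_train: float
    auc_test: float
    roc_train: RocCurve
    roc_test: RocCurve


@dataclass(frozen=True)
class BootstrapEvaluation:
    spec: ModelSpec
    n_boot: int
    fpr_grid: np.ndarray          # common FPR grid (101 points)
    ib_curves: np.ndarray         # (n_boot, grid) interpolated TPR
    oob_curves: np.ndarray
    ib_auc: np.ndarray            # (n_boot,)
    oob_auc: np.ndarray
    ib_band: tuple                # (lower, upper) arrays over the grid
    oob_band: tuple
    ib_auc_interval: tuple        # (2.5%, 97.5%)
    oob_auc_interval: tuple

    @property
    def oob_interval_width(self) -> float:
        lo, hi = self.oob_auc_interval
        return float(hi - lo)


def _resolve_xy(dataset, ids=None):
    if isinstance(dataset, TidyDataset):
        ds = dataset if ids is None else dataset.subset(ids)
        return ds.X, ds.y
    raise TypeError("dataset must be a TidyDataset")


def evaluate_train_test(
    spec: ModelSpec,
    dataset: TidyDataset,
    split: SplitIndices,
    transform: str = "log10",
) -> TrainTestEvaluation:
    """Fit on the training rows only and score both partitions.

    Test rows never contribute to preprocessing statistics or fitting.
    """
    X_train, y_train = _resolve_xy(dataset, split.train_ids)
    X_test, y_test = _resolve_xy(dataset, split.test_ids)
    if len(np.unique(y_test)) < 2:
        raise ValueError("test set contains a single class; AUC_test undefined")
    state = fit_preprocessing(X_train, transform)
    model = fit_model(spec, apply_preprocessing(state, X_train), y_train)
    s_train = predict_scores(model, apply_preprocessing(state, X_train))
    s_test = predict_scores(model, apply_preprocessing(state, X_test))
    rt, re = roc_curve(y_train, s_train), roc_curve(y_test, s_test)
    return TrainTestEvaluation(
        spec=spec, auc_train=rt.area, auc_test=re.area, roc_train=rt, roc_test=re
    )


def _stratified_resample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of one with-replacement bootstrap draw, stratified by class."""
    parts = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        parts.append(rng.choice(idx, size=idx.size, replace=True))
    return np.concatenate(parts)


def bootstrap_evaluate(
    spec: ModelSpec,
    dataset: TidyDataset,
    transform: str = "log10",
    n_boot: int = 100,
    seed: int = 0,
    n_grid: int = 101,
    max_redraws: int = 10,
) -> BootstrapEvaluation:
    """IB/OOB bootstrap of a fixed-hyperparameter model on the complete data.

    Resampling is stratified by class so small datasets rarely produce a
    single-class OOB set; if one still occurs the resample is redrawn (with a
    logged message) up to ``max_redraws`` times. Preprocessing is refit on
    the IB rows of every resample. Sub-seeds derive from
    ``(seed, resample index)`` so any single resample is reproducible alone.
    """
    X, y = _resolve_xy(dataset)
    fpr_grid = np.linspace(0.0, 1.0, n_grid)
    ib_curves = np.empty((n_boot, n_grid))
    oob_curves = np.empty((n_boot, n_grid))
    ib_auc = np.empty(n_boot)
    oob_auc = np.empty(n_boot)

    for b in range(n_boot):
        rng = np.random.default_rng(subseed(seed, b))
        for attempt in range(max_redraws + 1):
            ib = _stratified_resample(y, rng)
            oob = np.setdiff1d(np.arange(y.size), ib)
            if oob.size >= 2 and len(np.unique(y[oob])) == 2:
                break
            logger.warning("resample %d attempt %d: degenerate OOB set; redrawing", b, attempt)
        else:
            raise RuntimeError(f"resample {b}: no valid OOB set after {max_redraws} redraws")

        state = fit_preprocessing(X[ib], transform)
        model_spec = ModelSpec(
            spec.family, dict(spec.hyperparameters), dict(spec.fixed_settings),
            seed=subseed(seed, b, 1),
        )
        model = fit_model(model_spec, apply_preprocessing(state, X[ib]), y[ib])
        s_ib = predict_scores(model, apply_preprocessing(state, X[ib]))
        s_oob = predict_scores(model, apply_preprocessing(state, X[oob]))
        rc_ib = roc_curve(y[ib], s_ib)
        rc_oob = roc_curve(y[oob], s_oob)
        ib_curves[b] = rc_ib.interpolate(fpr_grid)
        oob_curves[b] = rc_oob.interpolate(fpr_grid)
        ib_auc[b] = rc_ib.area
        oob_auc[b] = rc_oob.area

    def band(curves):
        return (np.percentile(curves, 2.5, axis=0), np.percentile(curves, 97.5, axis=0))

    def interval(values):
        return (float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5)))

    return BootstrapEvaluation(
        spec=spec,
        n_boot=n_boot,
        fpr_grid=fpr_grid,
        ib_curves=ib_curves,
        oob_curves=oob_curves,
        ib_auc=ib_auc,
        oob_auc=oob_auc,
        ib_band=band(ib_curves),
        oob_band=band(oob_curves),
        ib_auc_interval=interval(ib_auc),
        oob_auc_interval=interval(oob_auc),
    )


def summarise_runs(evaluations: dict) -> pd.DataFrame:
    """Flatten a {(dataset, family): (TrainTestEvaluation, BootstrapEvaluation|None)}
    grid into one row per cell with AUCs and bootstrap intervals."""
    if not evaluations:
        raise ValueError("no evaluations to summarise")
    rows = []
    for (ds_name, family), (tte, boot) in evaluations.items():
        row = {
            "dataset": ds_name,
            "family": family,
            "auc_train": tte.auc_train,
            "auc_test": tte.auc_test,
        }
        if boot is not None:
            row.update(
                ib_auc_lo=boot.ib_auc_interval[0],
                ib_auc_hi=boot.ib_auc_interval[1],
                oob_auc_lo=boot.oob_auc_interval[0],
                oob_auc_hi=boot.oob_auc_interval[1],
            )
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_auc_differences(summary: pd.DataFrame) -> pd.DataFrame:
    """Mean AUC_test difference (row family minus column family) across datasets."""
    pivot = summary.pivot(index="dataset", columns="family", values="auc_test")
    families = list(pivot.columns)
    out = pd.DataFrame(index=families, columns=families, dtype=float)
    for a in families:
        for b in families:
            out.loc[a, b] = float((pivot[a] - pivot[b]).mean())
    return out
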