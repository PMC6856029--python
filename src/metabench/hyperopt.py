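"""Monte-Carlo cross-validated hyperparameter search with Pareto/knee selection.

For every candidate hyperparameter setting the search computes:

* ``R²`` and ``AUC_full`` from a fit on all training data;
* ``Q²`` and ``AUC_CV`` - for each of 10 Monte-Carlo repartitions, out-of-fold
  predictions from stratified 5-fold cross-validation are pooled into one
  prediction vector, scored, and the 10 per-repartition values averaged.

The optimum is read off the (Q², |R²-Q²|) plane (or its AUC analogue): the
Pareto front of settings that maximise cross-validated performance while
minimising the train/validation gap is extracted, and the front's knee - the
point of maximal perpendicular distance from the chord joining the front's
extremes - is chosen when the knee is pronounced enough. Flat fronts fall
back to the setting closest to the |R²-Q²| = 0.2 overtraining rule of thumb.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .metrics import auc, coefficient_of_determination
from .models import FAMILIES, ModelSpec, fit_model, predict_scores

__all__ = [
    "HyperGrid",
    "GridPointResult",
    "CVSurface",
    "ParetoSelection",
    "default_grid",
    "mc_cv_evaluate",
    "pareto_front",
    "select_optimum",
    "subseed",
]

_COMPLEXITY_DIRECTION = {
    "n_latent": +1,
    "n_components": +1,
    "C": +1,
    "gamma": +1,
    "max_depth": +1,
    "min_leaf_fraction": -1,
    "n_neurons": +1,
    "learning_rate": +1,
}


def subseed(seed: int, *indices: int) -> int:
    """Counter-based sub-seed: deterministic, collision-resistant, < 2**31."""
    entropy = [int(seed)] + [int(i) for i in indices]
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class HyperGrid:
    """Ordered candidate values per hyperparameter axis for one family."""

    family: str
    axes: tuple  # tuple of (name, tuple-of-values)

    def __post_init__(self):
        info = FAMILIES[self.family]
        names = tuple(name for name, _ in self.axes)
        if set(names) != set(info.tunable):
            raise ValueError(
                f"{self.family} grid must cover axes {info.tunable}, got {names}"
            )
        for name, values in self.axes:
            if len(values) < 1:
                raise ValueError(f"axis {name!r} has no candidate values")

    def points(self) -> list[dict]:
        names = [name for name, _ in self.axes]
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(values for _, values in self.axes))
        ]

    def complexity_key(self, params: dict) -> tuple:
        """Sortable key: smaller means a simpler model (used for tie-breaks)."""
        key = []
        for name, values in self.axes:
            direction = _COMPLEXITY_DIRECTION.get(name, +1)
            key.append(direction * list(values).index(params[name]))
        return tuple(key)

    @property
    def size(self) -> int:
        return int(np.prod([len(values) for _, values in self.axes]))


def default_grid(family: str, n_features: int | None = None,
                 max_components: int | None = None) -> HyperGrid:
    """The package's default search grid for a family.

    ``max_components`` caps component-count axes (normally min(20, rank of the
    training matrix)); ``n_features`` is accepted for signature symmetry.
    """
    cap = 20 if max_components is None else max(2, min(20, int(max_components)))
    log_c = tuple(10.0 ** k for k in range(-2, 5))            # 1e-2 .. 1e4
    log_gamma = tuple(10.0 ** k for k in range(-5, 2))        # 1e-5 .. 1e1
    log_lr = tuple(10.0 ** k for k in np.linspace(-3, 0, 7))  # 1e-3 .. 1
    axes_by_family = {
        "PLS-DA": (("n_latent", tuple(range(1, cap + 1))),),
        "PCR": (("n_components", tuple(range(1, cap + 1))),),
        "PCLR": (("n_components", tuple(range(1, cap + 1))),),
        "SVM-Lin": (("C", log_c),),
        "SVM-RBF": (("C", log_c), ("gamma", log_gamma)),
        "RF": (
            ("max_depth", tuple(range(1, 11))),
            ("min_leaf_fraction", (0.01, 0.03, 0.05, 0.08, 0.11, 0.14, 0.17, 0.20)),
        ),
        "ANN-LS": (("n_neurons", tuple(range(1, 11))), ("learning_rate", log_lr)),
        "ANN-SS": (("n_neurons", tuple(range(1, 11))), ("learning_rate", log_lr)),
    }
    if family not in axes_by_family:
        raise ValueError(f"no default grid for family {family!r}")
    return HyperGrid(family=family, axes=axes_by_family[family])


@dataclass(frozen=True)
class GridPointResult:
    params: dict
    r2: float
    q2: float
    auc_full: float
    auc_cv: float
    q2_repartitions: tuple
    auc_cv_repartitions: tuple


@dataclass(frozen=True)
class CVSurface:
    """Per-grid-point metrics from the Monte-Carlo cross-validated search."""

    family: str
    records: tuple  # of GridPointResult
    grid: HyperGrid
    k: int
    repartitions: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            row = dict(rec.params)
            row.update(
                R2=rec.r2, Q2=rec.q2, AUC_full=rec.auc_full, AUC_CV=rec.auc_cv
            )
            rows.append(row)
        return pd.DataFrame(rows)


def _stratified_repartitions(y, k, repartitions, seed):
    """Fold index lists per repartition; identical across all grid points."""
    folds = []
    for rep in range(repartitions):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=subseed(seed, rep))
        folds.append(list(skf.split(np.zeros_like(y), y)))
    return folds


def mc_cv_evaluate(
    family: str,
    grid: HyperGrid,
    X_train: np.ndarray,
    y_train: np.ndarray,
    k: int = 5,
    repartitions: int = 10,
    seed: int = 0,
    fixed_settings: dict | None = None,
) -> CVSurface:
    """Evaluate every grid point under k-fold CV with Monte-Carlo repartitions.

    ``X_train`` is expected already preprocessed (the workflow scales the
    training block once, then cross-validates within it). Deterministic for a
    fixed seed; the same fold repartitions are reused for every grid point so
    settings are compared on identical data splits.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train).astype(int).ravel()
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < k:
        raise ValueError(
            f"smallest class has {class_counts.min()} samples; "
            f"stratified {k}-fold needs at least {k} per class"
        )
    fixed = fixed_settings or {}
    fold_sets = _stratified_repartitions(y, k, repartitions, seed)
    y_mean = float(y.mean())

    records = []
    for params in grid.points():
        full_spec = ModelSpec(family, params, fixed, seed=subseed(seed, 0))
        full_scores = predict_scores(fit_model(full_spec, X, y), X)
        r2 = coefficient_of_determination(y, full_scores)
        auc_full = auc(y, full_scores)

        q2_reps, auc_reps = [], []
        for rep, folds in enumerate(fold_sets):
            oof = np.empty_like(y, dtype=float)
            for f, (tr, te) in enumerate(folds):
                spec = ModelSpec(family, params, fixed, seed=subseed(seed, rep + 1, f))
                oof[te] = predict_scores(fit_model(spec, X[tr], y[tr]), X[te])
            q2_reps.append(coefficient_of_determination(y, oof, center=y_mean))
            auc_reps.append(auc(y, oof))

        records.append(GridPointResult(
            params=params,
            r2=r2,
            q2=float(np.mean(q2_reps)),
            auc_full=auc_full,
            auc_cv=float(np.mean(auc_reps)),
            q2_repartitions=tuple(q2_reps),
            auc_cv_repartitions=tuple(auc_reps),
        ))
    return CVSurface(
        family=family, records=tuple(records), grid=grid,
        k=k, repartitions=repartitions, seed=seed,
    )


def pareto_front(points) -> list[int]:
    """Indices of non-dominated points, sorted by the first coordinate.

    Each point is ``(performance, gap)``: higher performance is better, lower
    gap is better. Duplicated points collapse to one representative (the
    first occurrence).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("points must be a non-empty list of (performance, gap) pairs")
    n = len(pts)
    keep = []
    seen = set()
    for i in range(n):
        key = (pts[i, 0], pts[i, 1])
        if key in seen:
            continue
        dominated = False
        for j in range(n):
            if j == i:
                continue
            ge_perf = pts[j, 0] >= pts[i, 0]
            le_gap = pts[j, 1] <= pts[i, 1]
            strict = pts[j, 0] > pts[i, 0] or pts[j, 1] < pts[i, 1]
            if ge_perf and le_gap and strict:
                dominated = True
                break
        if not dominated:
            seen.add(key)
            keep.append(i)
    keep.sort(key=lambda i: (pts[i, 0], pts[i, 1]))
    return keep


@dataclass(frozen=True)
class ParetoSelection:
    """Outcome of the knee/fallback rule on one CV surface."""

    metric_basis: str
    points: tuple              # all (performance, gap) pairs, grid order
    front_indices: tuple       # indices into points, sorted by performance
    chosen_index: int
    rule: str                  # "inflection" or "fallback_0.2"
    params: dict
    knee_threshold: float
    fallback_line: float

    @property
    def front_points(self) -> list:
        return [self.points[i] for i in self.front_indices]

    def to_spec(self, family: str, fixed_settings: dict | None = None,
                seed: int = 0) -> ModelSpec:
        return ModelSpec(family, dict(self.params), fixed_settings or {}, seed=seed)


def _surface_points(surface: CVSurface, metric_basis: str):
    if metric_basis == "R2Q2":
        return [(rec.q2, abs(rec.r2 - rec.q2)) for rec in surface.records]
    if metric_basis == "AUC":
        return [(rec.auc_cv, abs(rec.auc_full - rec.auc_cv)) for rec in surface.records]
    raise ValueError("metric_basis must be 'R2Q2' or 'AUC'")


def select_optimum(
    surface: CVSurface,
    metric_basis: str | None = None,
    knee_threshold: float = 0.02,
    fallback_line: float = 0.2,
) -> ParetoSelection:
    """Choose the optimal hyperparameter setting from a CV surface.

    The knee is the front point with maximal perpendicular distance to the
    chord joining the front's two extremes; it is accepted when that distance
    reaches ``knee_threshold`` (both axes are already commensurate, so the
    plane is used unnormalised). Otherwise - including degenerate fronts of
    fewer than three points - the rule falls back to the front point whose
    gap is closest to ``fallback_line``. All ties break toward the simpler
    model, making the selection invariant to grid-point ordering.
    """
    if metric_basis is None:
        metric_basis = FAMILIES[surface.family].default_basis
    points = _surface_points(surface, metric_basis)
    front = pareto_front(points)
    pts = np.asarray(points, dtype=float)
    complexity = [surface.grid.complexity_key(rec.params) for rec in surface.records]

    def simplest(candidates):
        return min(candidates, key=lambda i: (complexity[i], sorted(
            (k, repr(v)) for k, v in surface.records[i].params.items())))

    rule = "fallback_0.2"
    chosen = None
    if len(front) >= 3:
        p1, p2 = pts[front[0]], pts[front[-1]]
        chord = p2 - p1
        chord_len = np.linalg.norm(chord)
        if chord_len > 0:
            rel = pts[front] - p1
            dist = np.abs(chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / chord_len
            d_max = float(dist.max())
            if d_max >= knee_threshold:
                best = [front[i] for i in range(len(front))
                        if dist[i] >= d_max - 1e-12]
                chosen = simplest(best)
                rule = "inflection"
    if chosen is None:
        gaps = np.abs(pts[front, 1] - fallback_line)
        g_min = float(gaps.min())
        best = [front[i] for i in range(len(front)) if gaps[i] <= g_min + 1e-12]
        chosen = simplest(best)

    return ParetoSelection(
        metric_basis=metric_basis,
        points=tuple(map(tuple, points)),
        front_indices=tuple(front),
        chosen_index=int(chosen),
        rule=rule,
        params=dict(surface.records[chosen].params),
        knee_threshold=knee_threshold,
        fallback_line=fallback_line,
    )
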