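"""Tidy two-table feature-table I/O, stratified splitting, and preprocessing.

The on-disk convention is a workbook (or CSV pair) with two linked tables:

``Data``
    one row per sample: metadata columns (sample identifier, binary outcome,
    anything else) plus one column per metabolite, named ``M1``/``M_1`` style.
``Peak``
    one row per metabolite: the identifier used as a ``Data`` column name
    (``Name``), a human-readable annotation (``Label``), optional metadata.

All downstream modelling consumes the ``N x M`` intensity matrix ``X`` and the
binary outcome vector ``y`` exposed by :class:`TidyDataset`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("metabench")

__all__ = [
    "TidyDataset",
    "SplitIndices",
    "PreprocessingState",
    "TidyFormatError",
    "LinkageError",
    "OutcomeError",
    "read_tidy_workbook",
    "read_tidy_csv",
    "write_tidy_workbook",
    "write_tidy_csv",
    "stratified_split",
    "fit_preprocessing",
    "apply_preprocessing",
]

_METABOLITE_RE = re.compile(r"^M_?\d+$")


class TidyFormatError(ValueError):
    """The workbook does not follow the two-table convention."""


class LinkageError(TidyFormatError):
    """Data metabolite columns and Peak rows do not match one-to-one."""


class OutcomeError(TidyFormatError):
    """The outcome column is not a binary variable."""


@dataclass
class TidyDataset:
    """Paired Data/Peak tables holding X, y, and annotations.

    Parameters
    ----------
    data_table : pandas.DataFrame
        Samples by (metadata + metabolite) columns.
    peak_table : pandas.DataFrame
        Metabolites by (identifier ``Name``, annotation, optional metadata).
    outcome_column, sample_id_column : str
        Names of the binary class and unique sample identifier columns.
    positive_label : optional
        Outcome value mapped to 1; defaults to the lexicographically second
        of the two observed labels.
    """

    data_table: pd.DataFrame
    peak_table: pd.DataFrame
    outcome_column: str = "Class"
    sample_id_column: str = "SampleID"
    positive_label: object | None = None
    name: str = "dataset"

    # -- structure ---------------------------------------------------------

    @property
    def feature_names(self) -> list[str]:
        return [str(v) for v in self.peak_table["Name"]]

    @property
    def n_samples(self) -> int:
        return len(self.data_table)

    @property
    def n_features(self) -> int:
        return len(self.peak_table)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data_table[self.sample_id_column].to_numpy()

    @property
    def classes(self) -> tuple:
        """(negative_label, positive_label)."""
        labels = sorted(pd.unique(self.data_table[self.outcome_column]), key=str)
        if self.positive_label is None:
            return labels[0], labels[-1]
        neg = [l for l in labels if l != self.positive_label]
        return neg[0], self.positive_label

    @property
    def X(self) -> np.ndarray:
        """N x M intensity matrix (float, NaN for missing)."""
        return self.data_table[self.feature_names].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        """Binary outcome mapped to {0, 1}."""
        _, pos = self.classes
        return (self.data_table[self.outcome_column].to_numpy() == pos).astype(int)

    # -- validation --------------------------------------------------------

    def validate(self) -> "TidyDataset":
        """Check all structural invariants; return self for chaining."""
        for col in (self.sample_id_column, self.outcome_column):
            if col not in self.data_table.columns:
                raise TidyFormatError(f"Data table lacks required column {col!r}")
        if "Name" not in self.peak_table.columns:
            raise TidyFormatError("Peak table lacks required column 'Name'")

        peak_names = [str(v) for v in self.peak_table["Name"]]
        if len(set(peak_names)) != len(peak_names):
            raise LinkageError("duplicate metabolite identifiers in Peak table")
        data_cols = [str(c) for c in self.data_table.columns]
        metabolite_like = {
            c
            for c in data_cols
            if _METABOLITE_RE.match(c) and c not in (self.sample_id_column, self.outcome_column)
        }
        missing_in_data = [n for n in peak_names if n not in data_cols]
        if missing_in_data:
            raise LinkageError(
                f"Peak rows without matching Data columns: {missing_in_data[:5]}"
            )
        orphans = sorted(metabolite_like - set(peak_names))
        if orphans:
            raise LinkageError(
                f"Data metabolite columns without Peak rows: {orphans[:5]}"
            )

        ids = self.data_table[self.sample_id_column]
        if ids.duplicated().any():
            raise TidyFormatError("sample identifiers are not unique")

        outcome = self.data_table[self.outcome_column]
        labels = pd.unique(outcome.dropna())
        if len(labels) != 2:
            raise OutcomeError(
                f"outcome column {self.outcome_column!r} has {len(labels)} distinct "
                "values; exactly two are required"
            )
        if self.positive_label is not None and self.positive_label not in set(labels):
            raise OutcomeError(
                f"positive_label {self.positive_label!r} not among outcome values"
            )

        x = self.data_table[peak_names].to_numpy(dtype=float)
        if np.nanmin(x, initial=0.0) < 0:
            raise TidyFormatError("metabolite intensities must be non-negative or missing")
        return self

    def subset(self, sample_ids: Sequence) -> "TidyDataset":
        """Return a copy restricted to the given sample identifiers (in order)."""
        idx = self.data_table.set_index(self.sample_id_column, drop=False)
        sub = idx.loc[list(sample_ids)].reset_index(drop=True)
        return replace(self, data_table=sub)

    def equals(self, other: "TidyDataset") -> bool:
        return (
            self.data_table.equals(other.data_table)
            and self.peak_table.equals(other.peak_table)
            and self.outcome_column == other.outcome_column
            and self.sample_id_column == other.sample_id_column
        )


@dataclass(frozen=True)
class SplitIndices:
    """A stratified train/test partition recorded as sample identifiers."""

    train_ids: tuple
    test_ids: tuple
    seed: int

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")


def read_tidy_workbook(
    path,
    outcome_column: str = "Class",
    sample_id_column: str = "SampleID",
    positive_label=None,
    name: str | None = None,
) -> TidyDataset:
    """Read and validate a two-sheet Tidy workbook (sheets ``Data`` and ``Peak``)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sheets = pd.read_excel(path, sheet_name=None)
    for required in ("Data", "Peak"):
        if required not in sheets:
            raise TidyFormatError(
                f"workbook {path.name} lacks sheet {required!r}; found {list(sheets)}"
            )
    ds = TidyDataset(
        data_table=sheets["Data"],
        peak_table=sheets["Peak"],
        outcome_column=outcome_column,
        sample_id_column=sample_id_column,
        positive_label=positive_label,
        name=name or path.stem,
    )
    return ds.validate()


def read_tidy_csv(
    data_path,
    peak_path,
    outcome_column: str = "Class",
    sample_id_column: str = "SampleID",
    positive_label=None,
    name: str | None = None,
) -> TidyDataset:
    """Read the same two tables from a pair of CSV files."""
    ds = TidyDataset(
        data_table=pd.read_csv(data_path),
        peak_table=pd.read_csv(peak_path),
        outcome_column=outcome_column,
        sample_id_column=sample_id_column,
        positive_label=positive_label,
        name=name or Path(data_path).stem,
    )
    return ds.validate()


def write_tidy_workbook(dataset: TidyDataset, path) -> None:
    """Write a validated dataset as a two-sheet workbook; round-trips exactly."""
    dataset.validate()
    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        dataset.data_table.to_excel(writer, sheet_name="Data", index=False)
        dataset.peak_table.to_excel(writer, sheet_name="Peak", index=False)


def write_tidy_csv(dataset: TidyDataset, data_path, peak_path) -> None:
    dataset.validate()
    dataset.data_table.to_csv(data_path, index=False)
    dataset.peak_table.to_csv(peak_path, index=False)


def stratified_split(
    dataset: TidyDataset, train_fraction: float = 2.0 / 3.0, seed: int = 0
) -> SplitIndices:
    """Stratified random train/test split.

    Per-class training counts are ``round(train_fraction * n_class)`` under
    round-half-even; the remainder forms the test set. Deterministic for a
    fixed seed, and the resulting identifier lists are reusable across all
    model families so that every method sees identical training data.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    y = dataset.y
    ids = dataset.sample_ids
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in (0, 1):
        cls_ids = ids[y == cls]
        if len(cls_ids) < 2:
            raise ValueError(
                f"class {cls} has {len(cls_ids)} samples; at least 2 required "
                "for a stratified split"
            )
        n_train = int(np.round(train_fraction * len(cls_ids)))
        n_train = min(max(n_train, 1), len(cls_ids) - 1)
        perm = rng.permutation(len(cls_ids))
        train.extend(cls_ids[perm[:n_train]])
        test.extend(cls_ids[perm[n_train:]])
    return SplitIndices(train_ids=tuple(train), test_ids=tuple(test), seed=seed)


@dataclass
class PreprocessingState:
    """Train-derived transform/impute/scale statistics.

    All statistics are computed from training rows only; applying the state to
    any other matrix uses exclusively these frozen statistics (no leakage).
    """

    transform: str
    medians: np.ndarray      # imputation value per original feature (transformed scale)
    centre: np.ndarray       # per original feature
    scale: np.ndarray        # per original feature (population sd)
    kept: np.ndarray         # boolean mask over original features
    n_features_in: int = field(default=0)

    @property
    def n_features_out(self) -> int:
        return int(self.kept.sum())


def _transform(X: np.ndarray, transform: str) -> np.ndarray:
    if transform == "none":
        return X.astype(float, copy=True)
    if transform == "log10":
        if np.nanmin(X, initial=np.inf) <= 0:
            raise ValueError("log10 transform requires strictly positive intensities")
        return np.log10(X)
    raise ValueError(f"unknown transform {transform!r}")


def fit_preprocessing(X_train: np.ndarray, transform: str = "log10") -> PreprocessingState:
    """Fit transform + median imputation + autoscaling on training rows.

    Features with zero variance (or no observed values) after transformation
    are dropped with a logged warning rather than raising, since bootstrap
    resamples of small datasets routinely produce them.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim != 2 or X_train.shape[0] < 2:
        raise ValueError("X_train must be 2-D with at least 2 rows")
    T = _transform(X_train, transform)
    with np.errstate(all="ignore"):
        medians = np.nanmedian(T, axis=0)
    filled = np.where(np.isnan(T), medians, T)
    centre = np.nanmean(filled, axis=0)
    scale = np.nanstd(filled, axis=0)  # population sd: autoscale to unit variance
    kept = np.isfinite(scale) & (scale > 1e-12) & np.isfinite(medians)
    n_dropped = int((~kept).sum())
    if n_dropped:
        logger.warning(
            "dropping %d zero-variance or unobserved feature(s) during preprocessing",
            n_dropped,
        )
    if not kept.any():
        raise ValueError("no features remain after dropping zero-variance columns")
    return PreprocessingState(
        transform=transform,
        medians=medians,
        centre=centre,
        scale=scale,
        kept=kept,
        n_features_in=X_train.shape[1],
    )


def apply_preprocessing(state: PreprocessingState, X: np.ndarray) -> np.ndarray:
    """Apply frozen training statistics to any matrix with matching features."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != state.n_features_in:
        raise ValueError(
            f"expected {state.n_features_in} features, got {X.shape[1] if X.ndim == 2 else '?'}"
        )
    T = _transform(X, state.transform)
    T = np.where(np.isnan(T), state.medians, T)
    Z = (T - state.centre) / np.where(state.kept, state.scale, 1.0)
    return Z[:, state.kept]
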