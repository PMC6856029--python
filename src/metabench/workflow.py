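"""End-to-end workflow: split -> optimise -> evaluate -> bootstrap -> report.

The user-facing surface follows the modelling-object convention: a
:class:`ClassifierBenchmark` is built from data (one or more Tidy datasets)
plus a :class:`RunConfig`; ``fit()`` executes the full per-dataset x
per-family workflow and returns a :class:`BenchmarkResults` carrying the
selected hyperparameters, train/test AUCs, bootstrap intervals, and a
``summary()`` table. ``run_workflow`` wraps the same machinery behind a
config-file entry point for the command line.

The default configuration reproduces the study settings: a stratified 2:1
train/test split shared by every family, 5-fold cross-validation with 10
Monte-Carlo repartitions, the |R²-Q²| = 0.2 fallback line, and 100
bootstrap resamples.
"""

from __future__ import annotations

import json
import logging
import re
import traceback
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bootstrap import (
    BootstrapEvaluation,
    TrainTestEvaluation,
    bootstrap_evaluate,
    evaluate_train_test,
    pairwise_auc_differences,
    summarise_runs,
)
from .dataset import (
    TidyDataset,
    apply_preprocessing,
    fit_preprocessing,
    read_tidy_workbook,
    stratified_split,
)
from .hyperopt import (
    CVSurface,
    HyperGrid,
    ParetoSelection,
    default_grid,
    mc_cv_evaluate,
    select_optimum,
    subseed,
)
from .models import FAMILIES, effective_rank
from .synthetic import SyntheticSpec, generate_dataset

logger = logging.getLogger("metabench")

__all__ = [
    "RunConfig",
    "CellResult",
    "BenchmarkResults",
    "ClassifierBenchmark",
    "run_workflow",
    "fetch_accession_stub",
]

DEFAULT_FAMILIES = tuple(FAMILIES)


@dataclass
class RunConfig:
    """All knobs of the workflow; defaults reproduce the study settings."""

    families: tuple = DEFAULT_FAMILIES
    train_fraction: float = 2.0 / 3.0
    split_seed: int = 0
    seed: int = 0
    cv_k: int = 5
    cv_repartitions: int = 10
    n_boot: int = 100
    transform: str = "log10"
    metric_basis: str | None = None      # None: per-family default basis
    knee_threshold: float = 0.02
    fallback_line: float = 0.2
    outcome_column: str = "Class"
    sample_id_column: str = "SampleID"
    positive_label: object | None = None
    grid_overrides: dict = field(default_factory=dict)  # family -> {axis: [values]}
    dataset_paths: tuple = ()
    synthetic_specs: tuple = ()          # of dicts understood by SyntheticSpec
    output_dir: str | None = None

    def __post_init__(self):
        self.families = tuple(self.families)
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown families: {sorted(unknown)}")

    def grid_for(self, family: str, max_components: int | None = None) -> HyperGrid:
        override = self.grid_overrides.get(family)
        if override:
            tunable = FAMILIES[family].tunable
            if set(override) >= set(tunable):
                axes = tuple((name, tuple(override[name])) for name in tunable)
            else:
                base = default_grid(family, max_components=max_components)
                axes = tuple(
                    (name, tuple(override.get(name, values)))
                    for name, values in base.axes
                )
            return HyperGrid(family=family, axes=axes)
        return default_grid(family, max_components=max_components)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class CellResult:
    """Everything computed for one (dataset, family) cell."""

    dataset: str
    family: str
    surface: CVSurface | None = None
    selection: ParetoSelection | None = None
    train_test: TrainTestEvaluation | None = None
    bootstrap: BootstrapEvaluation | None = None
    error: str | None = None

    @property
    def ok(self) -> bool:
        return self.error is None


class BenchmarkResults:
    """Results object: estimates, intervals, diagnostics, and export."""

    def __init__(self, cells: list[CellResult], config: RunConfig, splits: dict):
        self.cells = cells
        self.config = config
        self.splits = splits

    def summary(self) -> pd.DataFrame:
        """One row per (dataset, family): chosen setting, rule, AUCs, intervals."""
        rows = []
        for cell in self.cells:
            row = {"dataset": cell.dataset, "family": cell.family}
            if cell.ok:
                row.update(
                    params=json.dumps(cell.selection.params, sort_keys=True),
                    selection_rule=cell.selection.rule,
                    metric_basis=cell.selection.metric_basis,
                    auc_train=cell.train_test.auc_train,
                    auc_test=cell.train_test.auc_test,
                )
                if cell.bootstrap is not None:
                    row.update(
                        ib_auc_lo=cell.bootstrap.ib_auc_interval[0],
                        ib_auc_hi=cell.bootstrap.ib_auc_interval[1],
                        oob_auc_lo=cell.bootstrap.oob_auc_interval[0],
                        oob_auc_hi=cell.bootstrap.oob_auc_interval[1],
                    )
            else:
                row["error"] = cell.error
            rows.append(row)
        return pd.DataFrame(rows)

    def pairwise_differences(self) -> pd.DataFrame:
        good = {
            (c.dataset, c.family): (c.train_test, c.bootstrap)
            for c in self.cells
            if c.ok
        }
        return pairwise_auc_differences(summarise_runs(good))

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_yaml(out / "resolved_config.yaml")
        self.summary().to_csv(out / "summary.csv", index=False)
        for cell in self.cells:
            stem = f"{cell.dataset}__{cell.family}".replace("/", "_")
            if not cell.ok:
                (out / f"{stem}.error.txt").write_text(cell.error)
                continue
            cell.surface.to_frame().to_csv(out / f"{stem}.cv_surface.csv", index=False)
            payload = {
                "selection": {
                    "params": cell.selection.params,
                    "rule": cell.selection.rule,
                    "metric_basis": cell.selection.metric_basis,
                    "front": [list(p) for p in cell.selection.front_points],
                },
                "auc_train": cell.train_test.auc_train,
                "auc_test": cell.train_test.auc_test,
            }
            if cell.bootstrap is not None:
                payload["ib_auc_interval"] = list(cell.bootstrap.ib_auc_interval)
                payload["oob_auc_interval"] = list(cell.bootstrap.oob_auc_interval)
            (out / f"{stem}.evaluation.json").write_text(json.dumps(payload, indent=2))
        return out


class ClassifierBenchmark:
    """The workflow as a fittable model object.

    Parameters
    ----------
    datasets : TidyDataset or mapping of name -> TidyDataset
    config : RunConfig, optional
    """

    def __init__(self, datasets, config: RunConfig | None = None):
        if isinstance(datasets, TidyDataset):
            datasets = {datasets.name: datasets}
        if not datasets:
            raise ValueError("at least one dataset is required")
        self.datasets = dict(datasets)
        self.config = config or RunConfig()

    def fit(self) -> BenchmarkResults:
        cfg = self.config
        cells: list[CellResult] = []
        splits = {}
        for ds_name, ds in self.datasets.items():
            split = stratified_split(ds, cfg.train_fraction, cfg.split_seed)
            splits[ds_name] = split
            train = ds.subset(split.train_ids)
            state = fit_preprocessing(train.X, cfg.transform)
            X_train = apply_preprocessing(state, train.X)
            y_train = train.y
            max_comp = min(20, effective_rank(X_train - X_train.mean(axis=0)))
            for family in cfg.families:
                cell = CellResult(dataset=ds_name, family=family)
                try:
                    grid = cfg.grid_for(family, max_components=max_comp)
                    cell.surface = mc_cv_evaluate(
                        family, grid, X_train, y_train,
                        k=cfg.cv_k, repartitions=cfg.cv_repartitions,
                        seed=subseed(cfg.seed, zlib.crc32(ds_name.encode()) % 2**16),
                    )
                    cell.selection = select_optimum(
                        cell.surface,
                        metric_basis=cfg.metric_basis,
                        knee_threshold=cfg.knee_threshold,
                        fallback_line=cfg.fallback_line,
                    )
                    spec = cell.selection.to_spec(
                        family, seed=subseed(cfg.seed, 1)
                    )
                    logger.info(
                        "%s/%s: selected %s by %s", ds_name, family,
                        cell.selection.params, cell.selection.rule,
                    )
                    cell.train_test = evaluate_train_test(
                        spec, ds, split, transform=cfg.transform
                    )
                    if cfg.n_boot > 0:
                        cell.bootstrap = bootstrap_evaluate(
                            spec, ds, transform=cfg.transform,
                            n_boot=cfg.n_boot, seed=subseed(cfg.seed, 2),
                        )
                except Exception as exc:  # per-cell isolation: grid keeps running
                    logger.exception("%s/%s failed", ds_name, family)
                    cell.error = f"{type(exc).__name__}: {exc}\n{traceback.format_exc()}"
                cells.append(cell)
        return BenchmarkResults(cells, cfg, splits)


def _load_datasets(config: RunConfig) -> dict[str, TidyDataset]:
    datasets: dict[str, TidyDataset] = {}
    for path in config.dataset_paths:
        ds = read_tidy_workbook(
            path,
            outcome_column=config.outcome_column,
            sample_id_column=config.sample_id_column,
            positive_label=config.positive_label,
        )
        datasets[ds.name] = ds
    for raw in config.synthetic_specs:
        ds = generate_dataset(SyntheticSpec(**dict(raw)))
        datasets[ds.name] = ds
    return datasets


def run_workflow(config: RunConfig) -> BenchmarkResults:
    """Load/generate the configured datasets, run the benchmark, save artifacts."""
    datasets = _load_datasets(config)
    results = ClassifierBenchmark(datasets, config).fit()
    if config.output_dir:
        results.save(config.output_dir)
    return results


_ACCESSION_RE = re.compile(r"^(MTBLS\d+|ST\d+)$")

_ACCESSION_TEMPLATE = """\
Accession {accession} ({repository})

This tool never downloads study data itself. To use this accession:

1. Retrieve the study from {url}.
2. Convert it to the two-table Tidy workbook convention:
   sheet "Data"  - one row per sample: SampleID, Class (binary outcome),
                   plus one intensity column per metabolite (M1, M2, ...);
   sheet "Peak"  - one row per metabolite: Idx, Name (matching the Data
                   column), Label (annotation).
3. Save it as: data/{accession}.xlsx
4. Point the run config at it:
     dataset_paths: ["data/{accession}.xlsx"]
"""


def fetch_accession_stub(accession: str) -> str:
    """Template describing how to supply a manually downloaded accession.

    Recognises MetaboLights (``MTBLS<n>``) and Metabolomics Workbench
    (``ST<n>``) identifiers; performs no network access.
    """
    if not _ACCESSION_RE.match(accession):
        raise ValueError(
            f"unrecognised accession {accession!r}; expected MTBLS<digits> or ST<digits>"
        )
    if accession.startswith("MTBLS"):
        repo, url = "MetaboLights", f"https://www.ebi.ac.uk/metabolights/{accession}"
    else:
        repo, url = (
            "Metabolomics Workbench",
            f"https://www.metabolomicsworkbench.org/data/DRCCMetadata.php?StudyID={accession}",
        )
    return _ACCESSION_TEMPLATE.format(accession=accession, repository=repo, url=url)
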