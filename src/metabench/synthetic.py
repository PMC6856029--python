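"""Synthetic Tidy-format feature tables with latent low-rank covariance.

Metabolomics feature tables carry strong inter-metabolite covariance: a few
latent biological factors drive many measured intensities. The generator
emulates exactly that structure. Latent scores ``T`` (n x r) are drawn per
class under one of three scenarios, projected through a seeded loading
matrix ``W`` (m x r), given multiplicative log-normal noise, and
exponentiated into positive intensities:

    X = exp(intensity_scale + T @ W.T + eps),   eps ~ N(0, feature_noise_sd)

Scenarios
---------
linear
    Each class mean shifted by +/- ``effect_size`` along latent axis 1 with
    unit within-class latent variance: the standard two-Gaussian design,
    linearly separable in latent space with population
    AUC = Phi(sqrt(2) * effect_size).
nonlinear_radial
    Class decided by the latent norm: controls sit in a central cloud,
    cases on a shell at radius >= effect_size. Radially, not linearly,
    separable.
nonlinear_xor
    Class decided by the sign parity of T1*T2 (quadrant XOR); no linear
    decision rule beats chance.

Class counts are exact (classes are assigned first, latent draws are made
conditional on class), missing cells are inserted completely at random, and
everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from .dataset import TidyDataset
from .hyperopt import subseed

__all__ = ["SyntheticSpec", "generate_dataset", "generate_benchmark_suite"]

_SCENARIOS = ("linear", "nonlinear_radial", "nonlinear_xor")


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters for one synthetic feature table."""

    n_samples: int = 200
    n_features: int = 100
    class_balance: float = 0.5       # fraction of positive (class 1) samples
    latent_rank: int = 2
    effect_size: float = 2.0         # class separation in latent units
    scenario: str = "linear"
    feature_noise_sd: float = 0.1    # sd of eps on the log-intensity scale
    missing_fraction: float = 0.0
    intensity_scale: float = 4.0     # baseline log intensity
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 4 or self.n_features < 1 or self.latent_rank < 1:
            raise ValueError("all counts must be positive (and n_samples >= 4)")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if not 0.0 <= self.missing_fraction < 0.5:
            raise ValueError("missing_fraction must lie in [0, 0.5)")
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}")
        if self.scenario == "nonlinear_xor" and self.latent_rank < 2:
            raise ValueError("nonlinear_xor requires latent_rank >= 2")

    def to_dict(self) -> dict:
        return asdict(self)


def _latent_scores(spec: SyntheticSpec, y: np.ndarray, rng: np.random.Generator):
    n, r = y.size, spec.latent_rank
    T = rng.standard_normal((n, r))
    if spec.scenario == "linear":
        T[:, 0] += np.where(y == 1, 1.0, -1.0) * spec.effect_size
    elif spec.scenario == "nonlinear_radial":
        cases = np.flatnonzero(y == 1)
        direction = rng.standard_normal((cases.size, r))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        radius = spec.effect_size + np.abs(rng.standard_normal(cases.size))
        T[cases] = direction * radius[:, None]
    else:  # nonlinear_xor: same-sign quadrants are cases, mixed-sign controls
        sign1 = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        sign2 = np.where(y == 1, sign1, -sign1)
        T[:, 0] = sign1 * np.abs(T[:, 0])
        T[:, 1] = sign2 * np.abs(T[:, 1])
    return T


def generate_dataset(spec: SyntheticSpec) -> TidyDataset:
    """Generate one Tidy dataset; passes full tidy validation by construction."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_samples, spec.n_features
    n_pos = int(np.round(spec.class_balance * n))
    if n_pos < 2 or n - n_pos < 2:
        raise ValueError(
            f"class balance {spec.class_balance} with n={n} leaves a class "
            "with fewer than 2 samples"
        )
    y = np.zeros(n, dtype=int)
    y[rng.permutation(n)[:n_pos]] = 1

    T = _latent_scores(spec, y, rng)
    W = rng.standard_normal((m, spec.latent_rank))
    log_x = (
        spec.intensity_scale
        + T @ W.T
        + spec.feature_noise_sd * rng.standard_normal((n, m))
    )
    X = np.exp(log_x)
    if spec.missing_fraction > 0:
        X = np.where(rng.random((n, m)) < spec.missing_fraction, np.nan, X)

    feature_names = [f"M{j + 1}" for j in range(m)]
    data = pd.DataFrame(X, columns=feature_names)
    data.insert(0, "SampleID", [f"S{i + 1:04d}" for i in range(n)])
    data.insert(1, "Class", y)
    peak = pd.DataFrame(
        {
            "Idx": np.arange(1, m + 1),
            "Name": feature_names,
            "Label": [f"Metabolite_{j + 1}" for j in range(m)],
        }
    )
    ds = TidyDataset(
        data_table=data,
        peak_table=peak,
        outcome_column="Class",
        sample_id_column="SampleID",
        positive_label=1,
        name=f"synthetic-{spec.scenario}-n{n}-seed{spec.seed}",
    )
    return ds.validate()


def generate_benchmark_suite(
    base: SyntheticSpec, n_values, scenarios
) -> dict[str, TidyDataset]:
    """One dataset per (n, scenario), with seeds derived from the base seed.

    Mirrors a multi-study benchmark sweep spanning small to large cohorts.
    """
    n_values = list(n_values)
    scenarios = list(scenarios)
    if not n_values or not scenarios:
        raise ValueError("n_values and scenarios must be non-empty")
    suite = {}
    for i, scenario in enumerate(scenarios):
        for j, n in enumerate(n_values):
            spec = replace(
                base, n_samples=int(n), scenario=scenario,
                seed=subseed(base.seed, i, j),
            )
            ds = generate_dataset(spec)
            suite[ds.name] = ds
    return suite
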