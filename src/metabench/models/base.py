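"""Model family registry and the common fit/score interface.

Every family is addressed by a :class:`ModelSpec` naming the family, its
tunable hyperparameters (exactly the set each family exposes), any fixed
settings, and a seed for the stochastic families. ``build_model`` turns a
spec into an untrained estimator with a uniform contract:

* ``fit(X, y)`` with preprocessed ``X`` and ``y`` in {0, 1};
* ``decision_scores(X)`` returning one finite continuous score per sample,
  oriented so that higher means more likely positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .ann import NeuralNetLS, NeuralNetSS
from .forest import RandomForest
from .linear import PCLR, PCR, PLSDA
from .svm import LinearSVM, RBFSVM

__all__ = [
    "ModelSpec",
    "FamilyInfo",
    "FAMILIES",
    "LINEAR_FAMILIES",
    "NONLINEAR_FAMILIES",
    "build_model",
    "fit_model",
    "predict_scores",
    "register_family",
]


@dataclass(frozen=True)
class FamilyInfo:
    name: str
    factory: Callable  # (hyperparameters, fixed_settings, seed) -> estimator
    tunable: tuple[str, ...]
    fixed_defaults: dict = field(default_factory=dict)
    default_basis: str = "R2Q2"    # metric basis used by hyperparameter selection
    stochastic: bool = False
    # per-hyperparameter direction of increasing model complexity:
    # +1 larger value is more complex, -1 smaller value is more complex
    complexity: dict = field(default_factory=dict)


def _positive(name, value):
    if value <= 0:
        raise ValueError(f"{name} must be positive, got {value}")
    return float(value)


def _positive_int(name, value):
    if int(value) != value or value < 1:
        raise ValueError(f"{name} must be an integer >= 1, got {value}")
    return int(value)


def _make_plsda(hp, fixed, seed):
    return PLSDA(n_latent=_positive_int("n_latent", hp["n_latent"]))


def _make_pcr(hp, fixed, seed):
    return PCR(n_components=_positive_int("n_components", hp["n_components"]))


def _make_pclr(hp, fixed, seed):
    return PCLR(n_components=_positive_int("n_components", hp["n_components"]))


def _make_svm_lin(hp, fixed, seed):
    return LinearSVM(C=_positive("C", hp["C"]))


def _make_svm_rbf(hp, fixed, seed):
    return RBFSVM(C=_positive("C", hp["C"]), gamma=_positive("gamma", hp["gamma"]))


def _make_rf(hp, fixed, seed):
    depth = _positive_int("max_depth", hp["max_depth"])
    frac = float(hp["min_leaf_fraction"])
    if not 0.0 < frac <= 0.5:
        raise ValueError(f"min_leaf_fraction must lie in (0, 0.5], got {frac}")
    return RandomForest(
        max_depth=depth,
        min_leaf_fraction=frac,
        seed=seed,
        n_trees=int(fixed.get("n_trees", 100)),
    )


def _make_ann(cls):
    def make(hp, fixed, seed):
        return cls(
            n_neurons=_positive_int("n_neurons", hp["n_neurons"]),
            learning_rate=_positive("learning_rate", hp["learning_rate"]),
            seed=seed,
            epochs=int(fixed.get("epochs", 400)),
            momentum=float(fixed.get("momentum", 0.5)),
            decay=float(fixed.get("decay", 0.0)),
        )

    return make


FAMILIES: dict[str, FamilyInfo] = {}


def register_family(info: FamilyInfo) -> FamilyInfo:
    FAMILIES[info.name] = info
    return info


register_family(FamilyInfo(
    "PLS-DA", _make_plsda, ("n_latent",), default_basis="R2Q2",
    complexity={"n_latent": +1},
))
register_family(FamilyInfo(
    "PCR", _make_pcr, ("n_components",), default_basis="R2Q2",
    complexity={"n_components": +1},
))
register_family(FamilyInfo(
    "PCLR", _make_pclr, ("n_components",), default_basis="R2Q2",
    complexity={"n_components": +1},
))
register_family(FamilyInfo(
    "SVM-Lin", _make_svm_lin, ("C",), default_basis="AUC",
    complexity={"C": +1},
))
register_family(FamilyInfo(
    "SVM-RBF", _make_svm_rbf, ("C", "gamma"), default_basis="AUC",
    complexity={"C": +1, "gamma": +1},
))
register_family(FamilyInfo(
    "RF", _make_rf, ("max_depth", "min_leaf_fraction"),
    fixed_defaults={"n_trees": 100}, default_basis="AUC", stochastic=True,
    complexity={"max_depth": +1, "min_leaf_fraction": -1},
))
register_family(FamilyInfo(
    "ANN-LS", _make_ann(NeuralNetLS), ("n_neurons", "learning_rate"),
    fixed_defaults={"momentum": 0.5, "decay": 0.0, "epochs": 400},
    default_basis="R2Q2", stochastic=True,
    complexity={"n_neurons": +1, "learning_rate": +1},
))
register_family(FamilyInfo(
    "ANN-SS", _make_ann(NeuralNetSS), ("n_neurons", "learning_rate"),
    fixed_defaults={"momentum": 0.5, "decay": 0.0, "epochs": 400},
    default_basis="R2Q2", stochastic=True,
    complexity={"n_neurons": +1, "learning_rate": +1},
))

LINEAR_FAMILIES = ("PLS-DA", "PCR", "PCLR", "SVM-Lin", "ANN-LS")
NONLINEAR_FAMILIES = ("SVM-RBF", "RF", "ANN-SS")


@dataclass(frozen=True)
class ModelSpec:
    """One model family with fixed hyperparameter values and a seed."""

    family: str
    hyperparameters: dict
    fixed_settings: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; known: {sorted(FAMILIES)}"
            )
        info = FAMILIES[self.family]
        got = set(self.hyperparameters)
        expected = set(info.tunable)
        if got != expected:
            raise ValueError(
                f"{self.family} expects hyperparameters {sorted(expected)}, got {sorted(got)}"
            )

    @property
    def info(self) -> FamilyInfo:
        return FAMILIES[self.family]

    def resolved_fixed(self) -> dict:
        merged = dict(self.info.fixed_defaults)
        merged.update(self.fixed_settings)
        return merged

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "hyperparameters": dict(self.hyperparameters),
            "fixed_settings": self.resolved_fixed(),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            family=d["family"],
            hyperparameters=dict(d["hyperparameters"]),
            fixed_settings=dict(d.get("fixed_settings", {})),
            seed=int(d.get("seed", 0)),
        )


def build_model(spec: ModelSpec):
    """Instantiate the untrained estimator a spec describes (validates values)."""
    info = FAMILIES[spec.family]
    return info.factory(spec.hyperparameters, spec.resolved_fixed(), spec.seed)


def fit_model(spec: ModelSpec, X_train, y_train):
    """Build and fit; deterministic given ``spec.seed``."""
    return build_model(spec).fit(X_train, y_train)


def predict_scores(fitted, X) -> np.ndarray:
    """Continuous per-sample scores, higher meaning more likely positive."""
    scores = np.asarray(fitted.decision_scores(X), dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("model produced non-finite scores")
    return scores
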