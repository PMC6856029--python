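"""Two-layer feed-forward networks trained by gradient descent with momentum.

Two variants share one implementation:

* ``ANN-LS`` - linear hidden neurons, single sigmoidal output;
* ``ANN-SS`` - sigmoidal hidden neurons, single sigmoidal output.

Training minimises mean binary cross-entropy by full-batch gradient descent
with momentum 0.5, learning-rate decay 0, for a fixed 400 epochs (all three
overridable through the spec's fixed settings). Weights are initialised from
a seeded uniform distribution scaled by the inverse square root of the
fan-in, so an identical seed reproduces the fit bit for bit.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

__all__ = ["TwoLayerNetwork", "NeuralNetLS", "NeuralNetSS"]

_PROB_EPS = 1e-12


class TwoLayerNetwork:
    def __init__(
        self,
        n_neurons: int,
        learning_rate: float,
        hidden_activation: str,
        seed: int = 0,
        epochs: int = 400,
        momentum: float = 0.5,
        decay: float = 0.0,
    ):
        if int(n_neurons) != n_neurons or n_neurons < 1:
            raise ValueError("n_neurons must be a positive integer")
        if learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if hidden_activation not in ("identity", "logistic"):
            raise ValueError("hidden_activation must be 'identity' or 'logistic'")
        if epochs < 0:
            raise ValueError("epochs must be non-negative")
        self.n_neurons = int(n_neurons)
        self.learning_rate = float(learning_rate)
        self.hidden_activation = hidden_activation
        self.seed = int(seed)
        self.epochs = int(epochs)
        self.momentum = float(momentum)
        self.decay = float(decay)

    # -- internals ---------------------------------------------------------

    def _hidden(self, A1: np.ndarray) -> np.ndarray:
        return A1 if self.hidden_activation == "identity" else expit(A1)

    def _forward(self, X: np.ndarray) -> np.ndarray:
        H = self._hidden(X @ self.W1_ + self.b1_)
        return expit(H @ self.W2_ + self.b2_)

    # -- api ----------------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X must be 2-D with one row per element of y")
        if len(np.unique(y)) < 2:
            raise ValueError("y_train contains a single class; cannot fit a classifier")
        n, m = X.shape
        h = self.n_neurons
        rng = np.random.default_rng(self.seed)
        self.W1_ = rng.uniform(-1.0, 1.0, size=(m, h)) / np.sqrt(m)
        self.b1_ = np.zeros(h)
        self.W2_ = rng.uniform(-1.0, 1.0, size=h) / np.sqrt(h)
        self.b2_ = 0.0

        vW1 = np.zeros_like(self.W1_)
        vb1 = np.zeros_like(self.b1_)
        vW2 = np.zeros_like(self.W2_)
        vb2 = 0.0

        for epoch in range(self.epochs):
            lr = self.learning_rate / (1.0 + self.decay * epoch)
            A1 = X @ self.W1_ + self.b1_
            H = self._hidden(A1)
            p = expit(H @ self.W2_ + self.b2_)

            # gradient of mean binary cross-entropy w.r.t. the output pre-activation
            d2 = (p - y) / n
            gW2 = H.T @ d2
            gb2 = d2.sum()
            dH = np.outer(d2, self.W2_)
            if self.hidden_activation == "logistic":
                dH = dH * H * (1.0 - H)
            gW1 = X.T @ dH
            gb1 = dH.sum(axis=0)

            vW1 = self.momentum * vW1 - lr * gW1
            vb1 = self.momentum * vb1 - lr * gb1
            vW2 = self.momentum * vW2 - lr * gW2
            vb2 = self.momentum * vb2 - lr * gb2
            self.W1_ += vW1
            self.b1_ += vb1
            self.W2_ += vW2
            self.b2_ += vb2

        self.n_features_in_ = m
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Predicted positive-class probabilities in the open interval (0, 1)."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(f"expected {self.n_features_in_} features, got {X.shape[1]}")
        return np.clip(self._forward(X), _PROB_EPS, 1.0 - _PROB_EPS)

    def cross_entropy(self, X, y) -> float:
        """Mean binary cross-entropy of the current weights on (X, y)."""
        p = self.decision_scores(X)
        y = np.asarray(y, dtype=float).ravel()
        return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class NeuralNetLS(TwoLayerNetwork):
    """Linear hidden layer, sigmoidal output (ANN-LS)."""

    def __init__(self, n_neurons, learning_rate, seed=0, epochs=400, momentum=0.5, decay=0.0):
        super().__init__(
            n_neurons, learning_rate, "identity", seed=seed, epochs=epochs,
            momentum=momentum, decay=decay,
        )


class NeuralNetSS(TwoLayerNetwork):
    """Sigmoidal hidden layer, sigmoidal output (ANN-SS)."""

    def __init__(self, n_neurons, learning_rate, seed=0, epochs=400, momentum=0.5, decay=0.0):
        super().__init__(
            n_neurons, learning_rate, "logistic", seed=seed, epochs=epochs,
            momentum=momentum, decay=decay,
        )
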