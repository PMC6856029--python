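import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import metabench as mb

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def linear_dataset():
    """A comfortably separable linear-scenario dataset reused across tests."""
    return mb.generate_dataset(
        mb.SyntheticSpec(n_samples=200, n_features=50, latent_rank=2,
                         effect_size=2.0, seed=42)
    )


@pytest.fixture(scope="session")
def preprocessed_training(linear_dataset):
    """(X_train, y_train) after the standard log10/autoscale preprocessing."""
    split = mb.stratified_split(linear_dataset, seed=7)
    train = linear_dataset.subset(split.train_ids)
    state = mb.fit_preprocessing(train.X, "log10")
    return mb.apply_preprocessing(state, train.X), train.y


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
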