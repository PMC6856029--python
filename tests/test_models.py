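"""The eight model families behind the common fit/score interface."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

import metabench as mb
from metabench.models import (
    FAMILIES,
    PCR,
    NeuralNetLS,
    NeuralNetSS,
    RandomForest,
    build_model,
    fit_model,
    predict_scores,
)

ALL_FAMILY_SPECS = {
    "PLS-DA": {"n_latent": 2},
    "PCR": {"n_components": 2},
    "PCLR": {"n_components": 2},
    "SVM-Lin": {"C": 1.0},
    "SVM-RBF": {"C": 1.0, "gamma": 0.01},
    "RF": {"max_depth": 3, "min_leaf_fraction": 0.05},
    "ANN-LS": {"n_neurons": 2, "learning_rate": 0.1},
    "ANN-SS": {"n_neurons": 4, "learning_rate": 0.5},
}


class TestPCA:
    def test_matches_svd_oracle(self, rng):
        X = rng.normal(size=(5, 3))
        X -= X.mean(axis=0)
        scores, loadings, explained = mb.pca_decompose(X, 3)
        s = np.linalg.svd(X, compute_uv=False)
        np.testing.assert_allclose(explained, s**2 / 4, atol=1e-10)
        np.testing.assert_allclose(loadings.T @ loadings, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(scores @ loadings.T, X, atol=1e-10)

    def test_single_direction_explains_everything(self, rng):
        t = rng.normal(size=10)
        t -= t.mean()
        X = np.outer(t, rng.normal(size=4))
        _, _, explained = mb.pca_decompose(X, 1)
        total = np.linalg.svd(X, compute_uv=False) ** 2 / 9
        assert explained[0] == pytest.approx(total.sum())

    def test_rank_error(self, rng):
        X = np.outer(rng.normal(size=6), rng.normal(size=4))
        with pytest.raises(ValueError, match="rank"):
            mb.pca_decompose(X - X.mean(0), 3)


class TestLinearEquivalences:
    def test_pcr_equals_regression_on_pca_scores(self, preprocessed_training):
        X, y = preprocessed_training
        k = 3
        model = PCR(n_components=k).fit(X, y)
        Xc = X - X.mean(axis=0)
        scores, _, _ = mb.pca_decompose(Xc, k)
        design = np.column_stack([np.ones(len(y)), scores])
        b, *_ = np.linalg.lstsq(design, y.astype(float), rcond=None)
        np.testing.assert_allclose(
            model.decision_scores(X), design @ b, atol=1e-8
        )

    def test_one_neuron_linear_ann_matches_logistic_regression_loss(self, rng):
        # a 1-linear-neuron + sigmoid-output network is an affine logit model,
        # so with enough epochs its cross-entropy approaches the ML optimum
        n = 120
        X = rng.normal(size=(n, 4))
        y = (X[:, 0] + rng.normal(scale=1.5, size=n) > 0).astype(int)
        net = NeuralNetLS(n_neurons=1, learning_rate=0.5, seed=0, epochs=4000).fit(X, y)
        lr = LogisticRegression(C=np.inf, solver="newton-cholesky", tol=1e-10)
        lr.fit(X, y)
        p = lr.predict_proba(X)[:, 1]
        lr_loss = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert net.cross_entropy(X, y) <= 1.05 * lr_loss


class TestKernels:
    def test_rbf_kernel_values(self):
        x = np.array([[0.0, 0.0]])
        y = np.array([[1.0, 0.0]])
        assert mb.rbf_kernel_matrix(x, x, 1.0)[0, 0] == pytest.approx(1.0)
        assert mb.rbf_kernel_matrix(x, y, 1.0)[0, 0] == pytest.approx(np.exp(-1.0))
        assert mb.rbf_kernel_matrix(x, y, 1e-9)[0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_rbf_kernel_symmetry_and_range(self, rng):
        A = rng.normal(size=(7, 3))
        K = mb.rbf_kernel_matrix(A, A, 0.5)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(K), 1.0)
        assert np.all((K > 0) & (K <= 1))

    def test_invalid_gamma(self):
        with pytest.raises(ValueError, match="gamma"):
            mb.rbf_kernel_matrix(np.eye(2), np.eye(2), 0.0)

    def test_linear_svm_separates_point_clouds(self, rng):
        X = np.vstack([rng.normal(size=(20, 2)) - 4, rng.normal(size=(20, 2)) + 4])
        y = np.array([0] * 20 + [1] * 20)
        spec = mb.ModelSpec("SVM-Lin", {"C": 1.0})
        scores = predict_scores(fit_model(spec, X, y), X)
        assert np.all(scores[y == 1] > 0) and np.all(scores[y == 0] < 0)


class TestRandomForestStructure:
    def test_depth_and_leaf_constraints(self, preprocessed_training):
        X, y = preprocessed_training
        rf = RandomForest(max_depth=3, min_leaf_fraction=0.1, seed=0).fit(X, y)
        assert max(rf.tree_depths()) <= 3
        floor = rf.min_samples_leaf_resolved(len(y))
        assert min(rf.min_leaf_counts()) >= floor


class TestNeuralNets:
    def test_zero_epochs_is_untrained_forward_pass(self, rng):
        # unstructured balanced data: an untrained net can only score at chance
        X = rng.normal(size=(200, 20))
        y = np.array([0, 1] * 100)
        spec = mb.ModelSpec(
            "ANN-SS", {"n_neurons": 3, "learning_rate": 0.1},
            fixed_settings={"epochs": 0}, seed=9,
        )
        trained = fit_model(spec, X, y)
        fresh = NeuralNetSS(n_neurons=3, learning_rate=0.1, seed=9, epochs=0).fit(X, y)
        np.testing.assert_array_equal(
            trained.decision_scores(X), fresh.decision_scores(X)
        )
        assert abs(mb.auc(y, trained.decision_scores(X)) - 0.5) < 3 * 0.6 / np.sqrt(100)

    def test_ann_default_fixed_settings(self):
        spec = mb.ModelSpec("ANN-LS", {"n_neurons": 2, "learning_rate": 0.1})
        model = build_model(spec)
        assert (model.epochs, model.momentum, model.decay) == (400, 0.5, 0.0)


class TestCommonContract:
    @pytest.mark.parametrize("family", sorted(ALL_FAMILY_SPECS))
    def test_scores_finite_and_auc_antisymmetric(self, family, preprocessed_training):
        X, y = preprocessed_training
        spec = mb.ModelSpec(family, ALL_FAMILY_SPECS[family], seed=3)
        scores = predict_scores(fit_model(spec, X, y), X)
        assert scores.shape == y.shape and np.all(np.isfinite(scores))
        a = mb.auc(y, scores)
        assert mb.auc(1 - y, scores) == pytest.approx(1.0 - a, abs=1e-12)

    @pytest.mark.parametrize("family", ["PLS-DA", "PCLR", "SVM-Lin"])
    def test_label_flip_reverses_ranking(self, family, preprocessed_training):
        X, y = preprocessed_training
        spec = mb.ModelSpec(family, ALL_FAMILY_SPECS[family], seed=3)
        a = mb.auc(y, predict_scores(fit_model(spec, X, y), X))
        a_flipped = mb.auc(1 - y, predict_scores(fit_model(spec, X, 1 - y), X))
        assert a > 0.5
        assert a_flipped == pytest.approx(a, abs=1e-6)

    @pytest.mark.parametrize("family", ["PCLR", "ANN-LS", "ANN-SS"])
    def test_probability_outputs_in_open_interval(self, family, preprocessed_training):
        X, y = preprocessed_training
        spec = mb.ModelSpec(family, ALL_FAMILY_SPECS[family], seed=1)
        scores = predict_scores(fit_model(spec, X, y), X)
        assert np.all((scores > 0) & (scores < 1))

    @pytest.mark.parametrize("family", ["RF", "ANN-LS", "ANN-SS"])
    def test_stochastic_families_bitwise_deterministic(self, family, preprocessed_training):
        X, y = preprocessed_training
        spec = mb.ModelSpec(family, ALL_FAMILY_SPECS[family], seed=7)
        s1 = predict_scores(fit_model(spec, X, y), X)
        s2 = predict_scores(fit_model(spec, X, y), X)
        np.testing.assert_array_equal(s1, s2)

    def test_feature_mismatch_raises(self, preprocessed_training):
        X, y = preprocessed_training
        model = fit_model(mb.ModelSpec("PLS-DA", {"n_latent": 1}), X, y)
        with pytest.raises(ValueError, match="features"):
            predict_scores(model, X[:, :-1])

    def test_single_class_fit_rejected(self, preprocessed_training):
        X, y = preprocessed_training
        spec = mb.ModelSpec("PLS-DA", {"n_latent": 1})
        with pytest.raises(ValueError, match="single class"):
            fit_model(spec, X, np.zeros_like(y))

    @pytest.mark.parametrize(
        "family, bad",
        [
            ("PLS-DA", {"n_latent": 0}),
            ("SVM-Lin", {"C": -1.0}),
            ("SVM-RBF", {"C": 1.0, "gamma": 0.0}),
            ("RF", {"max_depth": 2, "min_leaf_fraction": 0.7}),
            ("ANN-SS", {"n_neurons": 2, "learning_rate": 0.0}),
        ],
    )
    def test_invalid_hyperparameter_values_rejected(self, family, bad):
        with pytest.raises(ValueError):
            build_model(mb.ModelSpec(family, bad))

    def test_wrong_hyperparameter_names_rejected(self):
        with pytest.raises(ValueError, match="expects hyperparameters"):
            mb.ModelSpec("PLS-DA", {"components": 2})

    def test_spec_serialisation_round_trip(self):
        spec = mb.ModelSpec("SVM-RBF", {"C": 10.0, "gamma": 0.001}, seed=5)
        assert mb.ModelSpec.from_dict(spec.to_dict()) == mb.ModelSpec(
            "SVM-RBF", {"C": 10.0, "gamma": 0.001},
            fixed_settings=spec.resolved_fixed(), seed=5,
        )

    def test_registry_covers_the_eight_families(self):
        assert set(ALL_FAMILY_SPECS) <= set(FAMILIES)
        assert len(set(ALL_FAMILY_SPECS)) == 8
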