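"""Tidy two-table I/O, stratified splitting, and preprocessing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import metabench as mb
from metabench.dataset import LinkageError, OutcomeError, TidyFormatError


def make_dataset(n=6, m=3, labels=(0, 1)):
    names = [f"M{j + 1}" for j in range(m)]
    rng = np.random.default_rng(0)
    data = pd.DataFrame(rng.uniform(1, 100, size=(n, m)), columns=names)
    data.insert(0, "SampleID", [f"S{i}" for i in range(n)])
    data.insert(1, "Class", [labels[i % 2] for i in range(n)])
    peak = pd.DataFrame({"Name": names, "Label": [f"met {j}" for j in range(m)]})
    return mb.TidyDataset(data_table=data, peak_table=peak)


class TestWorkbookIO:
    def test_round_trip_xlsx(self, tmp_path):
        ds = make_dataset(4, 3).validate()
        path = tmp_path / "tiny.xlsx"
        mb.write_tidy_workbook(ds, path)
        back = mb.read_tidy_workbook(path)
        assert back.data_table.shape == ds.data_table.shape
        np.testing.assert_allclose(back.X, ds.X)
        assert list(back.feature_names) == list(ds.feature_names)
        # a second write/read of the re-read dataset is cell-for-cell identical
        path2 = tmp_path / "tiny2.xlsx"
        mb.write_tidy_workbook(back, path2)
        again = mb.read_tidy_workbook(path2)
        assert again.equals(back)

    def test_round_trip_csv(self, tmp_path):
        ds = make_dataset(5, 4).validate()
        mb.write_tidy_csv(ds, tmp_path / "d.csv", tmp_path / "p.csv")
        back = mb.read_tidy_csv(tmp_path / "d.csv", tmp_path / "p.csv")
        np.testing.assert_allclose(back.X, ds.X)

    def test_missing_sheet_is_format_error(self, tmp_path):
        path = tmp_path / "bad.xlsx"
        make_dataset().data_table.to_excel(path, sheet_name="Data", index=False)
        with pytest.raises(TidyFormatError):
            mb.read_tidy_workbook(path)

    @pytest.mark.parametrize("direction", ["extra_peak", "orphan_column"])
    def test_linkage_error_both_directions(self, direction):
        ds = make_dataset(4, 3)
        if direction == "extra_peak":
            ds.peak_table = pd.concat(
                [ds.peak_table, pd.DataFrame({"Name": ["M4"], "Label": ["x"]})],
                ignore_index=True,
            )
        else:
            ds.data_table["M4"] = 1.0
        with pytest.raises(LinkageError):
            ds.validate()

    def test_write_refuses_invalid_linkage(self, tmp_path):
        ds = make_dataset(4, 3)
        ds.data_table["M9"] = 1.0
        with pytest.raises(LinkageError):
            mb.write_tidy_workbook(ds, tmp_path / "never.xlsx")

    def test_non_binary_outcome_rejected(self):
        ds = make_dataset(6, 2, labels=(0, 1))
        ds.data_table.loc[0, "Class"] = 2
        with pytest.raises(OutcomeError):
            ds.validate()

    def test_duplicate_sample_ids_rejected(self):
        ds = make_dataset(4, 2)
        ds.data_table.loc[1, "SampleID"] = ds.data_table.loc[0, "SampleID"]
        with pytest.raises(TidyFormatError):
            ds.validate()

    def test_positive_label_mapping(self):
        ds = make_dataset(6, 2, labels=("healthy", "cancer")).validate()
        assert ds.classes == ("cancer", "healthy")  # lexicographic second -> positive
        flipped = mb.TidyDataset(
            ds.data_table, ds.peak_table, positive_label="cancer"
        ).validate()
        np.testing.assert_array_equal(flipped.y, 1 - ds.y)


class TestStratifiedSplit:
    def _counts(self, ds, split):
        train = ds.subset(split.train_ids)
        test = ds.subset(split.test_ids)
        return np.bincount(train.y, minlength=2), np.bincount(test.y, minlength=2)

    def test_table_sized_cohort_round_half_even(self):
        # a 184-sample cohort with classes 101/83 at 2:1 must train on 67+55
        spec = mb.SyntheticSpec(n_samples=184, class_balance=101 / 184,
                                n_features=5, seed=0)
        ds = mb.generate_dataset(spec)
        assert int(ds.y.sum()) == 101
        split = mb.stratified_split(ds, 2 / 3, seed=1)
        train_counts, test_counts = self._counts(ds, split)
        assert (train_counts[1], train_counts[0]) == (67, 55)
        assert (test_counts[1], test_counts[0]) == (34, 28)

    def test_tiny_unbalanced_classes(self):
        names = ["M1"]
        data = pd.DataFrame({
            "SampleID": [f"S{i}" for i in range(6)],
            "Class": [1, 1, 1, 1, 0, 0],
            "M1": np.arange(6) + 1.0,
        })
        peak = pd.DataFrame({"Name": names, "Label": names})
        ds = mb.TidyDataset(data, peak).validate()
        split = mb.stratified_split(ds, 2 / 3, seed=0)
        train_counts, test_counts = self._counts(ds, split)
        assert (train_counts[1], train_counts[0]) == (3, 1)
        assert (test_counts[1], test_counts[0]) == (1, 1)

    def test_deterministic_and_partition(self, linear_dataset):
        a = mb.stratified_split(linear_dataset, seed=5)
        b = mb.stratified_split(linear_dataset, seed=5)
        assert a == b
        ids = set(linear_dataset.sample_ids)
        assert set(a.train_ids) | set(a.test_ids) == ids
        assert set(a.train_ids) & set(a.test_ids) == set()

    def test_single_member_class_rejected(self):
        data = pd.DataFrame({
            "SampleID": ["a", "b", "c"], "Class": [0, 1, 1], "M1": [1.0, 2.0, 3.0]
        })
        peak = pd.DataFrame({"Name": ["M1"], "Label": ["m"]})
        ds = mb.TidyDataset(data, peak).validate()
        with pytest.raises(ValueError, match="at least 2"):
            mb.stratified_split(ds, 2 / 3, seed=0)

    @given(
        n_pos=st.integers(5, 120),
        n_neg=st.integers(5, 120),
        frac=st.floats(0.2, 0.8),
        seed=st.integers(0, 100),
    )
    def test_per_class_fraction_within_one_sample(self, n_pos, n_neg, frac, seed):
        n = n_pos + n_neg
        data = pd.DataFrame({
            "SampleID": [f"S{i}" for i in range(n)],
            "Class": [1] * n_pos + [0] * n_neg,
            "M1": np.linspace(1, 2, n),
        })
        peak = pd.DataFrame({"Name": ["M1"], "Label": ["m"]})
        ds = mb.TidyDataset(data, peak).validate()
        split = mb.stratified_split(ds, frac, seed=seed)
        train = ds.subset(split.train_ids)
        for cls, n_cls in ((1, n_pos), (0, n_neg)):
            got = int((train.y == cls).sum()) if cls == 1 else int((train.y == 0).sum())
            assert abs(got / n_cls - frac) <= 1.0 / n_cls + 1e-12


class TestPreprocessing:
    def test_log10_autoscale_hand_example(self):
        # {10, 100, 1000} -> log10 {1,2,3} -> autoscale with population sd
        X = np.array([[10.0], [100.0], [1000.0]])
        state = mb.fit_preprocessing(X, "log10")
        Z = mb.apply_preprocessing(state, X)
        expected = np.array([-1, 0, 1]) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(Z[:, 0], expected, atol=1e-12)

    def test_training_matrix_is_centred_and_scaled(self, linear_dataset):
        X = linear_dataset.X
        state = mb.fit_preprocessing(X, "log10")
        Z = mb.apply_preprocessing(state, X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-10)

    def test_zero_variance_features_dropped_with_warning(self, caplog):
        X = np.column_stack([np.ones(5), np.arange(5) + 1.0])
        with caplog.at_level("WARNING", logger="metabench"):
            state = mb.fit_preprocessing(X, "none")
        assert state.n_features_out == 1
        assert "zero-variance" in caplog.text

    def test_all_constant_features_is_error(self):
        with pytest.raises(ValueError, match="no features remain"):
            mb.fit_preprocessing(np.ones((4, 3)), "none")

    def test_log10_requires_positive_values(self):
        with pytest.raises(ValueError, match="positive"):
            mb.fit_preprocessing(np.array([[0.0], [1.0]]), "log10")

    def test_no_leakage_from_test_rows(self, rng):
        X_train = rng.uniform(1, 10, size=(20, 4))
        state = mb.fit_preprocessing(X_train, "log10")
        X_test_a = rng.uniform(1, 10, size=(8, 4))
        X_test_b = X_test_a * 1000  # wildly different test content
        Za = mb.apply_preprocessing(state, X_test_a)
        state2 = mb.fit_preprocessing(X_train, "log10")
        Za2 = mb.apply_preprocessing(state2, X_test_a)
        np.testing.assert_array_equal(Za, Za2)
        # statistics themselves never move, whatever is scored later
        mb.apply_preprocessing(state, X_test_b)
        np.testing.assert_array_equal(state.centre, state2.centre)

    def test_median_imputation_uses_training_median(self):
        X = np.array([[1.0, 5.0], [2.0, np.nan], [3.0, 7.0], [4.0, 9.0]])
        state = mb.fit_preprocessing(X, "none")
        Z_missing = mb.apply_preprocessing(state, np.array([[2.5, np.nan]]))
        Z_median = mb.apply_preprocessing(state, np.array([[2.5, 7.0]]))
        np.testing.assert_allclose(Z_missing, Z_median)
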