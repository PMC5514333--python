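"""Binary-relevance model: splits, training, prediction, persistence."""

import numpy as np
import pytest

from gomultiloc import (
    BinaryRelevanceModel,
    BinaryRelevanceResults,
    FixedK,
    FractionK,
    LabelSpace,
    MultiLabelDataset,
    Predictions,
    build_split,
    plain_br_model,
)
from gomultiloc.features import GOSubspace


class TestBuildSplit:
    def test_partition_matches_label_column(self, toy_dataset):
        split = build_split(toy_dataset, 0)
        assert split.positive_rows.tolist() == [0, 1]
        assert split.negative_rows.tolist() == [2]

    def test_multilocation_protein_positive_for_both_labels(self, toy_dataset):
        assert 1 in build_split(toy_dataset, 0).positive_rows
        assert 1 in build_split(toy_dataset, 1).positive_rows

    def test_partition_conserves_cohort(self, small_truth):
        dataset = small_truth.dataset
        for i in range(dataset.c):
            split = build_split(dataset, i)
            assert split.n_positive + split.n_negative == dataset.n
            assert split.n_positive == int((dataset.Y[:, i] == 1).sum())

    def test_single_class_label_raises_with_label_name(self):
        subspace = GOSubspace(["GO:A", "GO:B"])
        labelspace = LabelSpace(("everywhere", "nowhere"))
        dataset = MultiLabelDataset(
            ["P1", "P2"],
            np.array([[1, 0], [0, 1]]),
            np.array([[1, -1], [1, -1]]),
            subspace,
            labelspace,
        )
        with pytest.raises(ValueError, match="nowhere"):
            build_split(dataset, 1)


class TestFitPredict:
    def test_separable_toy_reaches_zero_training_error(self, toy_dataset):
        results = BinaryRelevanceModel(toy_dataset, k_policy=FixedK(2)).fit()
        assert results.train_errors == [0.0, 0.0]

    def test_training_positive_recovers_its_label(self, toy_dataset):
        results = BinaryRelevanceModel(toy_dataset, k_policy=FixedK(2)).fit()
        predictions = results.predict(toy_dataset.X)
        assert predictions.label_sets[0] == frozenset({"cytoplasm"})
        assert predictions.label_sets[1] == frozenset({"cytoplasm", "nucleus"})
        assert predictions.label_sets[2] == frozenset({"nucleus"})

    def test_full_selection_equivalent_to_plain_br(self, small_truth):
        dataset = small_truth.dataset
        specific = BinaryRelevanceModel(
            dataset, k_policy=FixedK(dataset.omega)
        ).fit()
        plain = plain_br_model(dataset).fit()
        assert np.allclose(
            specific.decision_scores(dataset.X), plain.decision_scores(dataset.X)
        )
        assert specific.predict(dataset.X).label_sets == (
            plain.predict(dataset.X).label_sets
        )

    def test_fit_twice_identical_predictions(self, small_truth):
        dataset = small_truth.dataset
        model = BinaryRelevanceModel(dataset, k_policy=FractionK(0.5))
        scores_a = model.fit().decision_scores(dataset.X)
        scores_b = model.fit().decision_scores(dataset.X)
        assert np.array_equal(scores_a, scores_b)

    def test_wrong_query_width_rejected(self, toy_dataset):
        results = BinaryRelevanceModel(toy_dataset, k_policy=FixedK(2)).fit()
        with pytest.raises(ValueError, match="omega"):
            results.predict(np.ones((1, 7)))

    def test_predict_terms_maps_raw_multiset(self, toy_dataset):
        results = BinaryRelevanceModel(toy_dataset, k_policy=FixedK(2)).fit()
        predictions = results.predict_terms({"GO:0000001": 3, "GO:0000099": 2})
        assert predictions.label_sets[0] == frozenset({"cytoplasm"})

    def test_zero_vector_query_flagged_but_predicted(self, toy_dataset):
        results = BinaryRelevanceModel(toy_dataset, k_policy=FixedK(2)).fit()
        predictions = results.predict(np.zeros((1, 3)))
        assert predictions.no_evidence[0]
        assert len(predictions.label_sets[0]) >= 1

    def test_untrainable_label_skipped_when_requested(self):
        subspace = GOSubspace(["GO:A", "GO:B"])
        labelspace = LabelSpace(("everywhere", "nowhere"))
        dataset = MultiLabelDataset(
            ["P1", "P2", "P3"],
            np.array([[3, 0], [0, 2], [1, 1]]),
            np.array([[1, -1], [1, -1], [1, -1]]),
            subspace,
            labelspace,
        )
        results = BinaryRelevanceModel(
            dataset, k_policy=FixedK(2), on_untrainable="skip"
        ).fit()
        assert results.estimators[1] is None
        predictions = results.predict(dataset.X)
        assert all(s == frozenset({"everywhere"}) for s in predictions.label_sets)

    def test_summary_reports_labels_and_k(self, toy_dataset):
        results = BinaryRelevanceModel(toy_dataset, k_policy=FixedK(2)).fit()
        text = results.summary()
        assert "cytoplasm" in text and "nucleus" in text
        assert "K" in text


class TestFallbackRule:
    def test_all_negative_scores_assign_single_best_label(self):
        predictions = Predictions(
            ("a", "b", "c"), np.array([[-3.0, -0.5, -2.0]])
        )
        assert predictions.label_sets[0] == frozenset({"b"})
        assert predictions.fallback[0]

    def test_positive_scores_collect_all_positive_labels(self):
        predictions = Predictions(("a", "b", "c"), np.array([[0.2, -1.0, 1.5]]))
        assert predictions.label_sets[0] == frozenset({"a", "c"})
        assert not predictions.fallback[0]

    def test_nan_scores_excluded_from_fallback(self):
        predictions = Predictions(
            ("a", "b"), np.array([[np.nan, -1.0]])
        )
        assert predictions.label_sets[0] == frozenset({"b"})

    def test_prediction_frame_joins_locations(self):
        predictions = Predictions(
            ("a", "b"), np.array([[1.0, 2.0]]), accessions=["Q1"]
        )
        frame = predictions.to_frame()
        assert frame.loc[0, "predicted_locations"] == "a;b"
        assert frame.loc[0, "accession"] == "Q1"


class TestPersistence:
    def test_save_load_roundtrip_identical_predictions(self, small_truth, tmp_path):
        dataset = small_truth.dataset
        results = BinaryRelevanceModel(dataset, k_policy=FractionK(0.3)).fit()
        before = results.decision_scores(dataset.X)
        path = tmp_path / "model.joblib"
        results.save(path)
        loaded = BinaryRelevanceResults.load(path)
        assert np.array_equal(loaded.decision_scores(dataset.X), before)
        assert loaded.labels == results.labels
        assert "loaded archive" in loaded.summary()

    def test_unsupported_archive_version_rejected(self, tmp_path):
        import joblib

        path = tmp_path / "bad.joblib"
        joblib.dump({"format_version": 99}, path)
        with pytest.raises(ValueError, match="version"):
            BinaryRelevanceResults.load(path)
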