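"""Example-based multilabel metrics and the jackknife protocol."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gomultiloc import (
    FixedK,
    FractionK,
    accuracy_by_cardinality,
    aggregate,
    jackknife,
    sample_metrics,
)

LABELS = ("a", "b", "c", "d")


def bitmask_metrics(y_mask: int, z_mask: int):
    """Independent oracle: set metrics by exhaustive bit counting."""
    inter = bin(y_mask & z_mask).count("1")
    union = bin(y_mask | z_mask).count("1")
    ny = bin(y_mask).count("1")
    nz = bin(z_mask).count("1")
    return (
        Fraction(inter, union),
        Fraction(inter, nz),
        Fraction(inter, ny),
        int(y_mask == z_mask),
    )


def mask_to_set(mask: int) -> frozenset:
    return frozenset(LABELS[i] for i in range(4) if mask >> i & 1)


class TestSampleMetrics:
    def test_hand_worked_overlap(self):
        assert sample_metrics({"A", "B"}, {"B", "C"}) == (
            pytest.approx(1 / 3),
            pytest.approx(1 / 2),
            pytest.approx(1 / 2),
            0,
        )

    def test_identical_sets_all_one(self):
        assert sample_metrics({"A"}, {"A"}) == (1, 1, 1, 1)

    def test_disjoint_sets_all_zero(self):
        assert sample_metrics({"A"}, {"B"}) == (0, 0, 0, 0)

    def test_empty_true_set_rejected(self):
        with pytest.raises(ValueError, match="true label set"):
            sample_metrics(set(), {"A"})

    def test_empty_prediction_rejected(self):
        with pytest.raises(ValueError, match="predicted"):
            sample_metrics({"A"}, set())

    @settings(derandomize=True, max_examples=120)
    @given(st.integers(1, 15), st.integers(1, 15))
    def test_matches_bitmask_enumeration(self, y_mask, z_mask):
        jaccard, precision, recall, exact = sample_metrics(
            mask_to_set(y_mask), mask_to_set(z_mask)
        )
        oj, op, orc, oe = bitmask_metrics(y_mask, z_mask)
        assert jaccard == pytest.approx(float(oj))
        assert precision == pytest.approx(float(op))
        assert recall == pytest.approx(float(orc))
        assert exact == oe


class TestAggregate:
    def test_hand_worked_example(self):
        report = aggregate([({"A", "B"}, {"B", "C"}), ({"A"}, {"A"})])
        assert report.mlacc == pytest.approx(2 / 3)
        assert report.mlpre == pytest.approx(3 / 4)
        assert report.mlrec == pytest.approx(3 / 4)
        assert report.acc == pytest.approx(1 / 2)
        assert report.mlf1_aggregate == pytest.approx(3 / 4)
        assert report.m == 2

    def test_all_perfect_predictions(self):
        report = aggregate([({"A"}, {"A"}), ({"B", "C"}, {"B", "C"})])
        for value in (report.mlacc, report.mlpre, report.mlrec,
                      report.mlf1, report.acc):
            assert value == 1.0

    def test_all_disjoint_predictions(self):
        report = aggregate([({"A"}, {"B"}), ({"C"}, {"D"})])
        for value in (report.mlacc, report.mlpre, report.mlrec,
                      report.mlf1, report.acc):
            assert value == 0.0

    def test_single_sample_reduces_to_per_sample_values(self):
        report = aggregate([({"A", "B"}, {"B", "C"})])
        assert report.mlacc == pytest.approx(1 / 3)
        assert report.acc == 0.0

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            aggregate([])

    @settings(derandomize=True, max_examples=60)
    @given(
        st.lists(
            st.tuples(st.integers(1, 15), st.integers(1, 15)),
            min_size=1,
            max_size=12,
        )
    )
    def test_metric_ordering_invariant(self, mask_pairs):
        samples = [(mask_to_set(y), mask_to_set(z)) for y, z in mask_pairs]
        report = aggregate(samples)
        assert report.acc <= report.mlacc + 1e-12
        assert report.mlacc <= min(report.mlpre, report.mlrec) + 1e-12
        for value in (report.mlacc, report.mlpre, report.mlrec,
                      report.mlf1, report.acc):
            assert 0.0 <= value <= 1.0

    def test_percent_formatting_two_decimals(self):
        report = aggregate([({"A", "B"}, {"B", "C"}), ({"A"}, {"A"})])
        pct = report.to_percent()
        assert pct["mlACC"] == 66.67
        assert pct["ACC"] == 50.0
        assert pct["m"] == 2

    def test_report_files_written(self, tmp_path):
        import json

        report = aggregate([({"A"}, {"A"})])
        report.save_json(tmp_path / "metrics.json")
        report.save_per_sample_tsv(tmp_path / "per_sample.tsv")
        payload = json.loads((tmp_path / "metrics.json").read_text())
        assert payload["ACC"] == 100.0
        assert "jaccard" in (tmp_path / "per_sample.tsv").read_text()


class TestAccuracyByCardinality:
    def test_all_single_label_correct(self):
        table = accuracy_by_cardinality([({"A"}, {"A"}), ({"B"}, {"B"})])
        assert table.to_dict("records") == [
            {"n_locations": 1, "n_proteins": 2, "acc_percent": 100.0}
        ]

    def test_grouping_by_true_cardinality(self):
        table = accuracy_by_cardinality(
            [({"A"}, {"A"}), ({"B"}, {"B"}), ({"A", "B"}, {"A"})]
        )
        assert table.to_dict("records") == [
            {"n_locations": 1, "n_proteins": 2, "acc_percent": 100.0},
            {"n_locations": 2, "n_proteins": 1, "acc_percent": 0.0},
        ]

    def test_group_counts_partition_the_samples(self, small_truth):
        dataset = small_truth.dataset
        samples = [
            (dataset.label_set(k), dataset.label_set(k))
            for k in range(dataset.n)
        ]
        table = accuracy_by_cardinality(samples)
        assert table["n_proteins"].sum() == dataset.n


class TestJackknife:
    def test_three_protein_toy_yields_three_folds(self, toy_dataset):
        report = jackknife(toy_dataset, k_policy=FixedK(2))
        assert report.m == toy_dataset.n == 3
        assert sorted(report.per_sample["accession"]) == ["P1", "P2", "P3"]

    def test_each_protein_evaluated_exactly_once(self, small_truth):
        report = jackknife(small_truth.dataset, k_policy=FractionK(0.5))
        assert report.per_sample["accession"].tolist() == (
            small_truth.dataset.accessions
        )

    def test_deterministic_config_repeats_identically(self, toy_dataset):
        first = jackknife(toy_dataset, k_policy=FixedK(2))
        second = jackknife(toy_dataset, k_policy=FixedK(2))
        assert first.to_dict() == second.to_dict()
        assert first.per_sample.equals(second.per_sample)

    def test_too_small_cohort_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="at least 3"):
            jackknife(toy_dataset.subset([0, 1]), k_policy=FixedK(1))

    def test_unknown_selection_mode_rejected(self, toy_dataset):
        with pytest.raises(ValueError, match="selection_mode"):
            jackknife(toy_dataset, selection_mode="magic")

    def test_label_losing_all_positives_is_skipped_not_fatal(self, caplog):
        import logging

        from gomultiloc import LabelSpace, MultiLabelDataset
        from gomultiloc.features import GOSubspace

        # 'endosome' has a single positive: the fold holding it out must
        # skip that label and still evaluate the protein on the rest.
        subspace = GOSubspace(["GO:A", "GO:B"])
        labelspace = LabelSpace(("cytoplasm", "endosome"))
        dataset = MultiLabelDataset(
            ["P1", "P2", "P3", "P4"],
            np.array([[3, 0], [2, 0], [0, 4], [3, 1]]),
            np.array([[1, -1], [1, -1], [-1, 1], [1, 1]]),
            subspace,
            labelspace,
        )
        with caplog.at_level(logging.WARNING):
            report = jackknife(dataset, k_policy=FixedK(2))
        assert report.m == 4
        assert "skipped" in caplog.text or "positives" in caplog.text

    def test_global_selection_mode_runs(self, toy_dataset):
        report = jackknife(
            toy_dataset, k_policy=FixedK(2), selection_mode="global"
        )
        assert report.m == 3
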