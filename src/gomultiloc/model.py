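"""Binary-relevance multilabel model over label-specific GO features.

The model follows the statsmodels convention: :class:`BinaryRelevanceModel`
is constructed from a :class:`~gomultiloc.dataset.MultiLabelDataset` (or
from annotation files via :meth:`BinaryRelevanceModel.from_files`), and
``fit()`` returns a :class:`BinaryRelevanceResults` object that carries
the per-label classifiers, the feature selection, training diagnostics,
``summary()``, prediction and serialization.

One binary classifier is trained per location label on the proteins
that do / do not reside there (±1 targets); with a label-specific
selection each classifier sees only its own top-K features, while
``FractionK(1.0)`` reduces the model to plain binary relevance on the
full feature set. A query's predicted location set collects the labels
whose classifiers score positive; if all score negative the single
best-scoring label is assigned so predictions are never empty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.svm import SVC

from .dataset import MultiLabelDataset, dataset_from_files
from .features import GOSubspace, vectorize
from .selection import (
    FractionK,
    InnerCVK,
    KPolicy,
    LabelSpecificSelection,
    select,
)

logger = logging.getLogger(__name__)

ARCHIVE_FORMAT_VERSION = 1


def default_base_learner(class_weight: str | None = None) -> SVC:
    """Linear-kernel SVM, C = 1.0 — the default per-label binary classifier."""
    return SVC(kernel="linear", C=1.0, class_weight=class_weight)


@dataclass(frozen=True)
class BinaryTrainingSplit:
    """±1 training partition for one label: positives in, everyone else out."""

    label_index: int
    positive_rows: np.ndarray
    negative_rows: np.ndarray

    @property
    def n_positive(self) -> int:
        return self.positive_rows.size

    @property
    def n_negative(self) -> int:
        return self.negative_rows.size


def build_split(dataset: MultiLabelDataset, label_index: int) -> BinaryTrainingSplit:
    """Partition the cohort into the positive/negative sets of one label."""
    y = dataset.Y[:, label_index]
    positive = np.flatnonzero(y == 1)
    negative = np.flatnonzero(y == -1)
    if positive.size == 0 or negative.size == 0:
        label = dataset.labelspace.labels[label_index]
        raise ValueError(
            f"label {label!r} is single-class "
            f"({positive.size} positive, {negative.size} negative): "
            "binary classifier untrainable"
        )
    return BinaryTrainingSplit(label_index, positive, negative)


class Predictions:
    """Per-query scores, predicted location sets and fallback flags."""

    def __init__(
        self,
        labels: tuple[str, ...],
        scores: np.ndarray,
        accessions: Sequence[str] | None = None,
    ):
        self.labels = labels
        self.scores = np.asarray(scores, dtype=float)
        n = self.scores.shape[0]
        self.accessions = list(accessions) if accessions is not None else [
            f"query{k}" for k in range(n)
        ]
        finite = np.isfinite(self.scores)
        positive = finite & (self.scores > 0)
        self.fallback = ~positive.any(axis=1)
        self.label_sets: list[frozenset[str]] = []
        for k in range(n):
            if self.fallback[k]:
                # all classifiers negative: assign the single best-scoring label
                row = np.where(finite[k], self.scores[k], -np.inf)
                chosen = {labels[int(np.argmax(row))]}
            else:
                chosen = {labels[i] for i in np.flatnonzero(positive[k])}
            self.label_sets.append(frozenset(chosen))

    def __len__(self) -> int:
        return len(self.label_sets)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.scores, columns=[f"score_{l}" for l in self.labels]
        )
        frame.insert(0, "accession", self.accessions)
        frame.insert(
            1,
            "predicted_locations",
            [";".join(sorted(s)) for s in self.label_sets],
        )
        frame["fallback"] = self.fallback
        return frame


class BinaryRelevanceModel:
    """Multilabel localization model specification.

    Parameters
    ----------
    dataset
        Training cohort: GO count matrix, ±1 label matrix, subspace.
    k_policy
        How many top-correlated features each label keeps. The default
        chooses K per label by inner cross-validation; ``FractionK(1.0)``
        gives the plain binary-relevance baseline (all features, no
        label-specific selection).
    base_learner
        Unfitted scikit-learn binary classifier exposing
        ``decision_function``; cloned once per label. Default: linear
        SVM, C = 1.0.
    ranking
        ``"absolute"`` ranks features by |r| (default), ``"signed"`` by r.
    selection
        Precomputed selection to reuse (bypasses ``k_policy``).
    on_untrainable
        ``"raise"`` (default) or ``"skip"`` a single-class label; a
        skipped label never appears in predictions.
    """

    def __init__(
        self,
        dataset: MultiLabelDataset,
        *,
        k_policy: KPolicy = InnerCVK(),
        base_learner=None,
        ranking: str = "absolute",
        selection: LabelSpecificSelection | None = None,
        on_untrainable: str = "raise",
    ):
        if on_untrainable not in ("raise", "skip"):
            raise ValueError("on_untrainable must be 'raise' or 'skip'")
        self.dataset = dataset
        self.k_policy = k_policy
        self.base_learner = (
            base_learner if base_learner is not None else default_base_learner()
        )
        self.ranking = ranking
        self.selection = selection
        self.on_untrainable = on_untrainable

    @classmethod
    def from_files(
        cls,
        gaf_path: str | Path,
        blast_path: str | Path,
        labels_path: str | Path,
        *,
        max_homologs: int = 1,
        evidence_exclude: Sequence[str] = (),
        **kwargs,
    ) -> "BinaryRelevanceModel":
        """Build the model straight from GAF / BLAST tabular / labels TSV."""
        dataset = dataset_from_files(
            gaf_path,
            blast_path,
            labels_path,
            max_homologs=max_homologs,
            evidence_exclude=evidence_exclude,
        )
        return cls(dataset, **kwargs)

    def fit(self) -> "BinaryRelevanceResults":
        """Select label-specific features and train one classifier per label."""
        dataset = self.dataset
        selection = self.selection
        if selection is None:
            selection = select(
                dataset,
                self.k_policy,
                base_learner=self.base_learner,
                ranking=self.ranking,
            )
        estimators: list = []
        train_errors: list[float] = []
        for i in range(dataset.c):
            try:
                build_split(dataset, i)
            except ValueError:
                if self.on_untrainable == "raise":
                    raise
                label = dataset.labelspace.labels[i]
                logger.warning("label %r single-class: classifier skipped", label)
                estimators.append(None)
                train_errors.append(np.nan)
                continue
            columns = selection.indices_for(i)
            estimator = clone(self.base_learner)
            estimator.fit(dataset.X[:, columns], dataset.Y[:, i])
            estimators.append(estimator)
            train_errors.append(
                float(
                    (estimator.predict(dataset.X[:, columns]) != dataset.Y[:, i]).mean()
                )
            )
        return BinaryRelevanceResults(self, selection, estimators, train_errors)


class BinaryRelevanceResults:
    """Fitted binary-relevance model: classifiers, selection, diagnostics."""

    def __init__(
        self,
        model: BinaryRelevanceModel,
        selection: LabelSpecificSelection,
        estimators: Sequence,
        train_errors: Sequence[float],
    ):
        self.model = model
        self.selection = selection
        self.estimators = list(estimators)
        self.train_errors = list(train_errors)
        self.subspace: GOSubspace = model.dataset.subspace
        self.labels: tuple[str, ...] = model.dataset.labelspace.labels

    # -- prediction ---------------------------------------------------------

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-label decision values for query rows (NaN for skipped labels)."""
        X = np.atleast_2d(np.asarray(X))
        if X.shape[1] != self.subspace.omega:
            raise ValueError(
                f"query vectors must have omega={self.subspace.omega} columns"
            )
        scores = np.full((X.shape[0], len(self.labels)), np.nan)
        for i, estimator in enumerate(self.estimators):
            if estimator is None:
                continue
            columns = self.selection.indices_for(i)
            scores[:, i] = estimator.decision_function(X[:, columns])
        return scores

    def predict(
        self, X: np.ndarray, accessions: Sequence[str] | None = None
    ) -> Predictions:
        """Predict location sets for query feature vectors (rows of ``X``).

        Queries whose vector is all zero carry no GO evidence; a
        prediction is still produced (and flagged via ``no_evidence``).
        """
        X = np.atleast_2d(np.asarray(X))
        predictions = Predictions(self.labels, self.decision_scores(X), accessions)
        predictions.no_evidence = ~(X != 0).any(axis=1)
        if predictions.no_evidence.any():
            logger.warning(
                "%d queries carry no GO evidence (all-zero vectors)",
                int(predictions.no_evidence.sum()),
            )
        return predictions

    def predict_terms(
        self, terms: Mapping[str, int], accession: str = "query"
    ) -> Predictions:
        """Predict from a raw GO term multiset (vectorized into the subspace)."""
        return self.predict(
            vectorize(terms, self.subspace)[None, :], [accession]
        )

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        """Plain-text per-label fit summary."""
        dataset = self.model.dataset
        lines = [
            "Binary-relevance GO localization model",
            f"  proteins: {dataset.n}   GO features (omega): {dataset.omega}   "
            f"labels: {dataset.c}",
            f"  base learner: {type(self.model.base_learner).__name__}   "
            f"K policy: {self.model.k_policy!r}",
            "",
            f"  {'label':<24}{'n_pos':>6}{'K':>6}{'max|r|':>9}{'train_err':>11}",
        ]
        for i, label in enumerate(self.labels):
            n_pos = int((dataset.Y[:, i] == 1).sum())
            r = self.selection.correlations[i]
            err = self.train_errors[i]
            lines.append(
                f"  {label:<24}{n_pos:>6}{self.selection.k_values[i]:>6}"
                f"{np.abs(r).max():>9.3f}"
                + (f"{err:>11.4f}" if np.isfinite(err) else f"{'skipped':>11}")
            )
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize the fitted model to a single-file archive."""
        payload = {
            "format_version": ARCHIVE_FORMAT_VERSION,
            "subspace_terms": self.subspace.terms,
            "labels": self.labels,
            "selection": self.selection,
            "estimators": self.estimators,
            "train_errors": self.train_errors,
            "config": {
                "k_policy": self.model.k_policy,
                "ranking": self.model.ranking,
                "base_learner": self.model.base_learner,
                "on_untrainable": self.model.on_untrainable,
            },
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "LoadedResults":
        payload = joblib.load(path)
        if payload.get("format_version") != ARCHIVE_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model archive version: {payload.get('format_version')}"
            )
        return LoadedResults(payload)


class LoadedResults(BinaryRelevanceResults):
    """Results reconstructed from an archive (no training dataset attached)."""

    def __init__(self, payload: dict):
        self.model = None  # type: ignore[assignment]
        self.selection = payload["selection"]
        self.estimators = payload["estimators"]
        self.train_errors = payload["train_errors"]
        self.subspace = GOSubspace(payload["subspace_terms"])
        self.labels = tuple(payload["labels"])
        self.config = payload["config"]

    def summary(self) -> str:
        lines = [
            "Binary-relevance GO localization model (loaded archive)",
            f"  GO features (omega): {self.subspace.omega}   labels: {len(self.labels)}",
        ]
        for i, label in enumerate(self.labels):
            lines.append(f"  {label:<24}K={self.selection.k_values[i]}")
        return "\n".join(lines)


def plain_br_model(dataset: MultiLabelDataset, **kwargs) -> BinaryRelevanceModel:
    """Plain binary-relevance baseline: every label uses all ω features."""
    kwargs.setdefault("k_policy", FractionK(1.0))
    return BinaryRelevanceModel(dataset, **kwargs)
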