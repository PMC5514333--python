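"""Example-based multilabel metrics and jackknife cross-validation.

Five example-based measures summarise a multilabel run over m samples
with true label sets Y_i and predicted sets Z_i:

    mlACC = mean Jaccard |Y∩Z| / |Y∪Z|
    mlPRE = mean |Y∩Z| / |Z|
    mlREC = mean |Y∩Z| / |Y|
    mlF1  = 2·mlPRE·mlREC / (mlPRE + mlREC)
    ACC   = mean exact-match indicator 1(Y ≡ Z)

ACC is the strictest: a sample counts only if the predicted set equals
the true set exactly. Two mlF1 conventions circulate — the harmonic
mean of the aggregate precision/recall above, and the mean of
per-sample F1 values; both are computed (``mlf1_aggregate`` is the
default ``mlf1``) because published tables are not always consistent
about which one they print.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import MultiLabelDataset
from .model import BinaryRelevanceModel, Predictions
from .selection import InnerCVK, KPolicy, LabelSpecificSelection, select

logger = logging.getLogger(__name__)

LabelSet = frozenset


def sample_metrics(Y: Iterable, Z: Iterable) -> tuple[float, float, float, int]:
    """Per-sample (jaccard, precision, recall, exact-match) for sets Y, Z."""
    Y, Z = frozenset(Y), frozenset(Z)
    if not Y:
        raise ValueError("true label set must be nonempty")
    if not Z:
        raise ValueError("predicted label set must be nonempty (fallback guarantees this)")
    intersection = len(Y & Z)
    return (
        intersection / len(Y | Z),
        intersection / len(Z),
        intersection / len(Y),
        int(Y == Z),
    )


@dataclass
class MetricsReport:
    """Aggregate example-based metrics over m evaluated samples.

    All metric attributes are proportions in [0, 1]; ``to_percent``
    formats them as percentages with two decimals.
    """

    m: int
    mlacc: float
    mlpre: float
    mlrec: float
    acc: float
    mlf1_aggregate: float
    mlf1_per_sample: float
    per_sample: pd.DataFrame = field(repr=False)

    @property
    def mlf1(self) -> float:
        """Default mlF1 display: harmonic mean of aggregate mlPRE and mlREC."""
        return self.mlf1_aggregate

    def to_dict(self) -> dict[str, float]:
        return {
            "m": self.m,
            "mlACC": self.mlacc,
            "mlPRE": self.mlpre,
            "mlREC": self.mlrec,
            "mlF1": self.mlf1_aggregate,
            "mlF1_per_sample": self.mlf1_per_sample,
            "ACC": self.acc,
        }

    def to_percent(self) -> dict[str, float]:
        """Metrics as percentages rounded to two decimals."""
        out = {}
        for key, value in self.to_dict().items():
            out[key] = value if key == "m" else round(100.0 * value, 2)
        return out

    def summary(self) -> str:
        pct = self.to_percent()
        lines = [f"Example-based multilabel metrics over m={self.m} samples"]
        for key in ("mlACC", "mlPRE", "mlREC", "mlF1", "mlF1_per_sample", "ACC"):
            lines.append(f"  {key:<16}{pct[key]:>8.2f} %")
        return "\n".join(lines)

    def save_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(self.to_percent(), handle, indent=1)

    def save_per_sample_tsv(self, path: str | Path) -> None:
        self.per_sample.to_csv(path, sep="\t", index=False)


def aggregate(
    samples: Sequence[tuple[Iterable, Iterable]],
    accessions: Sequence[str] | None = None,
) -> MetricsReport:
    """Aggregate per-sample metrics over (Y, Z) label-set pairs."""
    if not samples:
        raise ValueError("cannot aggregate zero samples")
    if accessions is None:
        accessions = [f"sample{k}" for k in range(len(samples))]
    rows = []
    for accession, (Y, Z) in zip(accessions, samples):
        jaccard, precision, recall, exact = sample_metrics(Y, Z)
        f1 = (
            0.0
            if precision + recall == 0
            else 2 * precision * recall / (precision + recall)
        )
        rows.append(
            {
                "accession": accession,
                "true_labels": ";".join(sorted(map(str, Y))),
                "predicted_labels": ";".join(sorted(map(str, Z))),
                "jaccard": jaccard,
                "precision": precision,
                "recall": recall,
                "f1": f1,
                "exact": exact,
            }
        )
    per_sample = pd.DataFrame(rows)
    mlpre = float(per_sample["precision"].mean())
    mlrec = float(per_sample["recall"].mean())
    return MetricsReport(
        m=len(samples),
        mlacc=float(per_sample["jaccard"].mean()),
        mlpre=mlpre,
        mlrec=mlrec,
        acc=float(per_sample["exact"].mean()),
        mlf1_aggregate=(
            0.0 if mlpre + mlrec == 0 else 2 * mlpre * mlrec / (mlpre + mlrec)
        ),
        mlf1_per_sample=float(per_sample["f1"].mean()),
        per_sample=per_sample,
    )


def accuracy_by_cardinality(
    samples: Sequence[tuple[Iterable, Iterable]]
) -> pd.DataFrame:
    """Exact-match accuracy grouped by the number of true locations |Y|."""
    if not samples:
        raise ValueError("cannot tabulate zero samples")
    rows = []
    for Y, Z in samples:
        _, _, _, exact = sample_metrics(Y, Z)
        rows.append({"n_locations": len(frozenset(Y)), "exact": exact})
    frame = pd.DataFrame(rows)
    grouped = (
        frame.groupby("n_locations")
        .agg(n_proteins=("exact", "size"), acc=("exact", "mean"))
        .reset_index()
    )
    grouped["acc_percent"] = (100.0 * grouped["acc"]).round(2)
    return grouped[["n_locations", "n_proteins", "acc_percent"]]


def jackknife(
    dataset: MultiLabelDataset,
    *,
    k_policy: KPolicy = InnerCVK(),
    base_learner=None,
    ranking: str = "absolute",
    selection_mode: str = "in-fold",
    progress: Callable[[int, int], None] | None = None,
) -> MetricsReport:
    """Leave-one-out evaluation of the full pipeline.

    The cohort of n proteins yields n folds; in each, one protein is
    held out and the remaining n−1 are used to re-run feature ranking,
    K selection and classifier training (``selection_mode="in-fold"``,
    the leakage-free default), or to retrain classifiers on a selection
    computed once from the full cohort (``selection_mode="global"``).
    The GO subspace is fixed throughout — it is part of the feature
    encoding, not of the classifier. A label that loses all positives
    (or negatives) inside a fold is skipped for that fold with a
    warning; prediction proceeds over the remaining labels.
    """
    if dataset.n < 3:
        raise ValueError("jackknife needs at least 3 proteins")
    if selection_mode not in ("in-fold", "global"):
        raise ValueError("selection_mode must be 'in-fold' or 'global'")
    positives_per_label = (dataset.Y == 1).sum(axis=0)
    if (positives_per_label < 2).any():
        scarce = [
            dataset.labelspace.labels[i]
            for i in np.flatnonzero(positives_per_label < 2)
        ]
        logger.warning(
            "labels with <2 positives will be skipped in some folds: %s", scarce
        )
    global_selection: LabelSpecificSelection | None = None
    if selection_mode == "global":
        global_selection = select(
            dataset, k_policy, base_learner=base_learner, ranking=ranking
        )
    samples: list[tuple[frozenset, frozenset]] = []
    for k in range(dataset.n):
        rows = np.delete(np.arange(dataset.n), k)
        training = dataset.subset(rows)
        model = BinaryRelevanceModel(
            training,
            k_policy=k_policy,
            base_learner=base_learner,
            ranking=ranking,
            selection=global_selection,
            on_untrainable="skip",
        )
        predictions: Predictions = model.fit().predict(
            dataset.X[k][None, :], [dataset.accessions[k]]
        )
        samples.append((dataset.label_set(k), predictions.label_sets[0]))
        if progress is not None:
            progress(k + 1, dataset.n)
    return aggregate(samples, accessions=dataset.accessions)
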