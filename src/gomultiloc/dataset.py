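"""Multilabel dataset container: GO count matrix plus a ±1 label matrix."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .features import GOSubspace, collect_cohort_terms, encode_matrix
from .io import parse_blast_tabular, parse_gaf, read_labels_tsv

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelSpace:
    """Ordered subcellular-location names λ₁…λ_c."""

    labels: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("label names must be distinct")
        if len(self.labels) < 2:
            raise ValueError("need at least two labels for multilabel learning")

    @property
    def c(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __len__(self) -> int:
        return len(self.labels)


class MultiLabelDataset:
    """n proteins x omega GO-count features with an n x c ±1 label matrix.

    Invariants enforced at construction: every protein carries at least
    one location (no all −1 rows in ``Y``) and at least one GO count (no
    all-zero rows in ``X``; a protein without GO evidence is
    unannotatable and must be excluded upstream).
    """

    def __init__(
        self,
        accessions: Sequence[str],
        X: np.ndarray,
        Y: np.ndarray,
        subspace: GOSubspace,
        labelspace: LabelSpace,
    ):
        X = np.asarray(X)
        Y = np.asarray(Y)
        n = len(accessions)
        if X.shape != (n, subspace.omega):
            raise ValueError(f"X must be {n} x {subspace.omega}, got {X.shape}")
        if Y.shape != (n, labelspace.c):
            raise ValueError(f"Y must be {n} x {labelspace.c}, got {Y.shape}")
        if not np.isin(Y, (-1, 1)).all():
            raise ValueError("Y entries must be +1 or -1")
        if np.any(X < 0):
            raise ValueError("X entries must be nonnegative counts")
        if n and not (Y == 1).any(axis=1).all():
            bad = [accessions[i] for i in np.flatnonzero(~(Y == 1).any(axis=1))]
            raise ValueError(f"proteins without any location: {bad[:5]}")
        if n and not (X > 0).any(axis=1).all():
            bad = [accessions[i] for i in np.flatnonzero(~(X > 0).any(axis=1))]
            raise ValueError(f"all-zero feature rows (no GO evidence): {bad[:5]}")
        self.accessions = list(accessions)
        self.X = X
        self.Y = Y.astype(np.int64)
        self.subspace = subspace
        self.labelspace = labelspace

    @property
    def n(self) -> int:
        return len(self.accessions)

    @property
    def omega(self) -> int:
        return self.subspace.omega

    @property
    def c(self) -> int:
        return self.labelspace.c

    def label_set(self, k: int) -> frozenset[str]:
        """The set of location names protein ``k`` belongs to."""
        return frozenset(
            self.labelspace.labels[i] for i in np.flatnonzero(self.Y[k] == 1)
        )

    def cardinalities(self) -> np.ndarray:
        """Number of locations per protein."""
        return (self.Y == 1).sum(axis=1)

    def subset(self, rows: Sequence[int]) -> "MultiLabelDataset":
        """Row-subset view sharing the same subspace and label space."""
        rows = np.asarray(rows, dtype=np.intp)
        return MultiLabelDataset(
            [self.accessions[i] for i in rows],
            self.X[rows],
            self.Y[rows],
            self.subspace,
            self.labelspace,
        )

    def __repr__(self) -> str:
        return (
            f"MultiLabelDataset(n={self.n}, omega={self.omega}, c={self.c})"
        )


def dataset_from_components(
    memberships: Mapping[str, Sequence[str]],
    multisets: Mapping[str, Mapping[str, int]],
    subspace: GOSubspace | None = None,
    labelspace: LabelSpace | None = None,
) -> MultiLabelDataset:
    """Assemble a dataset from label memberships and GO term multisets.

    Only accessions present in both maps enter the dataset; order follows
    the membership table.
    """
    accessions = [a for a in memberships if a in multisets]
    if not accessions:
        raise ValueError("no accession has both labels and GO terms")
    if subspace is None:
        subspace = GOSubspace(
            {t for a in accessions for t in multisets[a]}
        )
    if labelspace is None:
        labelspace = LabelSpace(
            tuple(sorted({l for a in accessions for l in memberships[a]}))
        )
    X = encode_matrix([multisets[a] for a in accessions], subspace)
    Y = -np.ones((len(accessions), labelspace.c), dtype=np.int64)
    for k, accession in enumerate(accessions):
        for label in memberships[accession]:
            Y[k, labelspace.index(label)] = 1
    return MultiLabelDataset(accessions, X, Y, subspace, labelspace)


def dataset_from_files(
    gaf_path: str | Path,
    blast_path: str | Path,
    labels_path: str | Path,
    *,
    max_homologs: int = 1,
    evidence_exclude: Sequence[str] = (),
    subspace: GOSubspace | None = None,
) -> MultiLabelDataset:
    """Build a dataset from GAF, BLAST tabular and label TSV files.

    Runs the full encoding pipeline: parse annotations and homology
    hits, homology-transfer a term multiset per labelled protein, build
    (or reuse) the GO subspace, and vectorize. Unannotatable proteins
    are dropped with a logged warning.
    """
    table = parse_gaf(gaf_path, evidence_exclude=evidence_exclude)
    homologs = parse_blast_tabular(blast_path)
    memberships = read_labels_tsv(labels_path)
    multisets, unannotatable = collect_cohort_terms(
        list(memberships), homologs, table, max_homologs=max_homologs
    )
    if unannotatable:
        logger.warning(
            "%d proteins unannotatable (no GO terms even after own-accession "
            "fallback), excluded: %s%s",
            len(unannotatable),
            ", ".join(unannotatable[:5]),
            "..." if len(unannotatable) > 5 else "",
        )
    return dataset_from_components(memberships, multisets, subspace=subspace)
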