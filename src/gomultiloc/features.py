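"""GO occurrence-count feature encoding with homology transfer.

A query protein is represented in a "GO subspace": the ordered set of
distinct GO terms observed across the training cohort. Its feature
vector counts how often each subspace term occurs among the annotations
of its top BLAST homologs (annotations of the protein's own accession
are used as a fallback when homology transfer yields nothing). Proteins
for which even the fallback yields no terms are "unannotatable" and are
excluded from datasets, so all-zero feature rows never enter training.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import GOAnnotationTable, HomologSet


class GOSubspace:
    """Ordered, distinct GO terms forming the feature coordinate system.

    Ordering is lexicographic by term identifier, which makes feature
    matrices reproducible across runs regardless of input order.
    """

    def __init__(self, terms: Iterable[str]):
        ordered = sorted(set(terms))
        if not ordered:
            raise ValueError("a GO subspace needs at least one term")
        self.terms: tuple[str, ...] = tuple(ordered)
        self.index: dict[str, int] = {t: i for i, t in enumerate(self.terms)}

    @property
    def omega(self) -> int:
        """Dimensionality of the feature space."""
        return len(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def __eq__(self, other) -> bool:
        if not isinstance(other, GOSubspace):
            return NotImplemented
        return self.terms == other.terms

    def __repr__(self) -> str:
        return f"GOSubspace(omega={self.omega})"


def collect_go_terms(
    accession: str,
    homologs: HomologSet,
    table: GOAnnotationTable,
    max_homologs: int = 1,
) -> Counter:
    """Homology-transfer the GO term multiset for one protein.

    The term multisets of the first ``max_homologs`` homologs (best
    e-value first) are accumulated with multiplicity. If the protein has
    no homologs, or none of the selected homologs carries any term, the
    protein's own annotation entry is used instead. The result may be
    empty, in which case the protein is unannotatable.
    """
    if max_homologs < 1:
        raise ValueError("max_homologs must be >= 1")
    collected: Counter = Counter()
    for hit in homologs.hits_for(accession)[:max_homologs]:
        collected.update(table.terms_for(hit.subject))
    if not collected:
        collected = table.terms_for(accession)
    return collected


def collect_cohort_terms(
    accessions: Sequence[str],
    homologs: HomologSet,
    table: GOAnnotationTable,
    max_homologs: int = 1,
) -> tuple[dict[str, Counter], list[str]]:
    """Collect term multisets for a cohort; returns (multisets, unannotatable)."""
    multisets: dict[str, Counter] = {}
    unannotatable: list[str] = []
    for accession in accessions:
        terms = collect_go_terms(accession, homologs, table, max_homologs)
        if terms:
            multisets[accession] = terms
        else:
            unannotatable.append(accession)
    return multisets, unannotatable


def build_subspace(term_multisets: Iterable[Mapping[str, int]]) -> GOSubspace:
    """Form the GO subspace from the distinct terms of a cohort."""
    union: set[str] = set()
    for multiset in term_multisets:
        union.update(multiset)
    if not union:
        raise ValueError("no GO terms in any multiset: cannot build a feature space")
    return GOSubspace(union)


def vectorize(terms: Mapping[str, int], subspace: GOSubspace) -> np.ndarray:
    """Occurrence-count feature vector of a term multiset in ``subspace``.

    Terms outside the subspace are silently dropped; they can arise at
    prediction time when a query carries GO terms unseen in training.
    """
    values = np.zeros(subspace.omega, dtype=np.int64)
    for term, count in terms.items():
        position = subspace.index.get(term)
        if position is not None:
            values[position] = count
    return values


def encode_matrix(
    multisets: Sequence[Mapping[str, int]], subspace: GOSubspace
) -> np.ndarray:
    """Stack :func:`vectorize` over a cohort into an n x omega count matrix."""
    if len(multisets) == 0:
        return np.zeros((0, subspace.omega), dtype=np.int64)
    return np.stack([vectorize(m, subspace) for m in multisets])
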