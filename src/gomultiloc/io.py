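"""Flat-file readers and writers for the annotation pipeline.

GO annotations arrive as GAF 2.x (tab-delimited, ``!``-prefixed comments);
homology hits arrive as 12-column BLAST tabular output (``-outfmt 6``).
Both are parsed into light in-memory maps keyed by protein accession.
Feature matrices are exported as dense TSV or MatrixMarket sparse
coordinates with a JSON sidecar naming the GO-term columns.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: GAF 2.x column positions (0-based) actually consumed.
_GAF_ACCESSION = 1   # DB Object ID
_GAF_GO_ID = 4       # GO ID
_GAF_EVIDENCE = 6    # Evidence Code
_GAF_MIN_COLUMNS = 15


class GOAnnotationTable:
    """Accession -> multiset of GO term identifiers.

    Lookups of unknown accessions return an empty multiset rather than
    failing: a protein simply has no GO evidence yet.
    """

    def __init__(self, entries: Mapping[str, Mapping[str, int]] | None = None):
        self._entries: dict[str, Counter] = {}
        for accession, terms in (entries or {}).items():
            counts = Counter(terms)
            for term, mult in counts.items():
                if not (isinstance(mult, (int, np.integer)) and mult > 0):
                    raise ValueError(
                        f"multiplicity for ({accession}, {term}) must be a "
                        f"positive integer, got {mult!r}"
                    )
            if counts:
                self._entries[accession] = counts

    def terms_for(self, accession: str) -> Counter:
        """Return the term multiset for ``accession`` (empty if unknown)."""
        return Counter(self._entries.get(accession, ()))

    def accessions(self) -> list[str]:
        return sorted(self._entries)

    def __contains__(self, accession: str) -> bool:
        return accession in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def __eq__(self, other) -> bool:
        if not isinstance(other, GOAnnotationTable):
            return NotImplemented
        return self._entries == other._entries


@dataclass(frozen=True)
class BlastHit:
    subject: str
    evalue: float
    bitscore: float


class HomologSet:
    """Query accession -> ordered homolog hits.

    Per query, hits are sorted ascending by e-value, ties broken by
    descending bit score then subject accession; self-hits are removed.
    """

    def __init__(self, hits: Mapping[str, Iterable[BlastHit]] | None = None):
        self._hits: dict[str, tuple[BlastHit, ...]] = {}
        for query, raw in (hits or {}).items():
            kept = [h for h in raw if h.subject != query]
            kept.sort(key=lambda h: (h.evalue, -h.bitscore, h.subject))
            if kept:
                self._hits[query] = tuple(kept)

    def hits_for(self, query: str) -> tuple[BlastHit, ...]:
        return self._hits.get(query, ())

    def queries(self) -> list[str]:
        return sorted(self._hits)

    def __contains__(self, query: str) -> bool:
        return query in self._hits

    def __len__(self) -> int:
        return len(self._hits)

    def __eq__(self, other) -> bool:
        if not isinstance(other, HomologSet):
            return NotImplemented
        return self._hits == other._hits


def parse_gaf(
    path: str | Path,
    evidence_exclude: Iterable[str] = (),
) -> GOAnnotationTable:
    """Parse a GAF 2.x file into a :class:`GOAnnotationTable`.

    One multiplicity increment per retained annotation row, keyed by the
    DB Object ID column; duplicate (accession, term) rows accumulate.
    Rows whose evidence code is in ``evidence_exclude`` are dropped;
    rows with fewer than 15 columns are skipped with a logged warning.
    """
    excluded = frozenset(evidence_exclude)
    entries: dict[str, Counter] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("!") or not line.strip():
                continue
            columns = line.rstrip("\n").split("\t")
            if len(columns) < _GAF_MIN_COLUMNS:
                logger.warning(
                    "%s:%d: malformed GAF row (%d columns), skipped",
                    path, lineno, len(columns),
                )
                continue
            if columns[_GAF_EVIDENCE] in excluded:
                continue
            accession = columns[_GAF_ACCESSION]
            term = columns[_GAF_GO_ID]
            entries.setdefault(accession, Counter())[term] += 1
    return GOAnnotationTable(entries)


def parse_blast_tabular(path: str | Path) -> HomologSet:
    """Parse 12-column BLAST ``-outfmt 6`` output into a :class:`HomologSet`.

    Columns used: qseqid (1), sseqid (2), evalue (11), bitscore (12).
    Rows with a non-numeric e-value or bit score are skipped with a
    logged warning.
    """
    hits: dict[str, list[BlastHit]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("#") or not line.strip():
                continue
            columns = line.rstrip("\n").split("\t")
            if len(columns) < 12:
                logger.warning(
                    "%s:%d: malformed BLAST row (%d columns), skipped",
                    path, lineno, len(columns),
                )
                continue
            try:
                evalue = float(columns[10])
                bitscore = float(columns[11])
            except ValueError:
                logger.warning(
                    "%s:%d: non-numeric e-value/bitscore, skipped", path, lineno
                )
                continue
            hits.setdefault(columns[0], []).append(
                BlastHit(subject=columns[1], evalue=evalue, bitscore=bitscore)
            )
    return HomologSet(hits)


def read_labels_tsv(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a membership table: ``accession<TAB>loc1;loc2;...`` per line."""
    memberships: dict[str, tuple[str, ...]] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[1]:
                raise ValueError(f"{path}:{lineno}: expected 'accession<TAB>locations'")
            labels = tuple(x for x in parts[1].split(";") if x)
            if not labels:
                raise ValueError(f"{path}:{lineno}: empty label set for {parts[0]}")
            memberships[parts[0]] = labels
    return memberships


def write_labels_tsv(memberships: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for accession in memberships:
            handle.write(f"{accession}\t{';'.join(memberships[accession])}\n")


def write_feature_matrix_tsv(
    accessions: Sequence[str],
    X: np.ndarray,
    terms: Sequence[str],
    path: str | Path,
) -> None:
    """Write the dense accession x GO-term count matrix as TSV."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("accession\t" + "\t".join(terms) + "\n")
        for accession, row in zip(accessions, X):
            handle.write(accession + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_feature_matrix_sparse(
    accessions: Sequence[str],
    X: np.ndarray,
    terms: Sequence[str],
    matrix_path: str | Path,
    sidecar_path: str | Path,
) -> None:
    """Write the count matrix in MatrixMarket coordinate form.

    A JSON sidecar records the row accessions and the ordered GO-term
    columns so the sparse file is self-describing.
    """
    scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(np.asarray(X)))
    with open(sidecar_path, "w", encoding="utf-8") as handle:
        json.dump(
            {"accessions": list(accessions), "terms": list(terms)},
            handle,
            indent=1,
        )
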