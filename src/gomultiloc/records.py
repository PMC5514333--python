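"""Benchmark-dataset curation filters for Swiss-Prot-style protein records.

The benchmark construction keeps only full-length, unambiguous sequences
whose subcellular locations were determined experimentally: fragments are
dropped, as are sequences shorter than 50 residues (likely fragments),
sequences containing the ambiguity letters B, X or Z, and location
annotations inferred "by similarity" from homologs (a record losing all
its locations is dropped entirely).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

MIN_SEQUENCE_LENGTH = 50
AMBIGUOUS_LETTERS = frozenset("BXZ")

#: Evidence tag for locations determined by direct experiment.
EXPERIMENTAL = "experimental"
#: Evidence tag for locations transferred from homologous proteins.
BY_SIMILARITY = "by_similarity"


@dataclass(frozen=True)
class LocationAnnotation:
    name: str
    evidence: str = EXPERIMENTAL


@dataclass(frozen=True)
class ProteinRecord:
    """A flat protein record as curated from a Swiss-Prot-style source."""

    accession: str
    sequence: str
    locations: tuple[LocationAnnotation, ...] = ()
    is_fragment: bool = False
    keywords: tuple[str, ...] = ()


def filter_records(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Apply the benchmark curation rules, returning the retained records.

    Retained records carry only their experimentally determined locations.
    """
    kept: list[ProteinRecord] = []
    for record in records:
        if record.is_fragment:
            continue
        if len(record.sequence) < MIN_SEQUENCE_LENGTH:
            continue
        if AMBIGUOUS_LETTERS.intersection(record.sequence):
            continue
        experimental = tuple(
            loc for loc in record.locations if loc.evidence == EXPERIMENTAL
        )
        if not experimental:
            continue
        kept.append(replace(record, locations=experimental))
    return kept
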