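"""Seeded synthetic multilabel GO-like benchmark generator.

Emulates the structure of a homology-transferred GO benchmark for
apoptosis-protein localization without any database access: sparse
nonnegative integer GO-occurrence feature vectors, overlapping label
sets whose cardinality profile follows the real benchmark (majority
single-location, a long tail up to six locations), and per-label
planted "signal" GO terms whose occurrence rate is elevated for
proteins carrying that label. Matching GAF / BLAST-tabular / labels-TSV
fixture files can be written so the full parsing-and-encoding pipeline
is exercised end to end; parsing them back reproduces the generated
count matrix exactly.

Counts are Poisson draws: every term occurs at background rate λ₀, and
each label adds an independent Poisson(Δλ) increment on its own s
signal terms for the proteins holding that label. Δλ = 0 turns the
signal off and gives a pure null model.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import LabelSpace, MultiLabelDataset
from .features import GOSubspace
from .io import BlastHit, GOAnnotationTable, HomologSet, write_labels_tsv

#: Observed benchmark cardinality profile: proteins in 1..6 locations.
CARDINALITY_PROFILE = (303, 155, 52, 6, 1, 1)

#: The eight benchmark compartments, used as default label names.
COMPARTMENTS = (
    "cytoplasm",
    "membrane",
    "secreted",
    "mitochondrion",
    "nucleus",
    "endosome",
    "endoplasmic_reticulum",
    "golgi_apparatus",
)


def default_cardinality_dist(c: int) -> tuple[float, ...]:
    """The benchmark cardinality profile truncated to c labels, normalized."""
    counts = CARDINALITY_PROFILE[: min(c, len(CARDINALITY_PROFILE))]
    total = sum(counts)
    return tuple(x / total for x in counts)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generation parameters for a synthetic GO-like multilabel cohort.

    Defaults mirror the real benchmark's shape: 518 proteins over 8
    compartments with the observed location-count profile; 160 distinct
    GO terms with 5 planted signal terms per compartment; background
    occurrence rate λ₀ = 0.5 and signal increment Δλ = 3.
    """

    n: int = 518
    c: int = 8
    omega: int = 160
    s: int = 5
    lam0: float = 0.5
    dlam: float = 3.0
    cardinality_dist: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n < 1 or self.c < 2 or self.omega < 1 or self.s < 0:
            raise ValueError("n >= 1, c >= 2, omega >= 1, s >= 0 required")
        if self.s * self.c > self.omega:
            raise ValueError(
                f"s*c = {self.s * self.c} planted terms exceed omega = {self.omega}"
            )
        if self.lam0 < 0 or self.dlam < 0:
            raise ValueError("rates must be nonnegative")
        if self.cardinality_dist is not None:
            dist = tuple(self.cardinality_dist)
            if len(dist) > self.c:
                raise ValueError(
                    f"cardinality support {len(dist)} exceeds label count {self.c}"
                )
            if any(p < 0 for p in dist) or abs(sum(dist) - 1.0) > 1e-9:
                raise ValueError("cardinality_dist must be a probability vector")
            object.__setattr__(self, "cardinality_dist", dist)
        if self.lam0 == 0 and (self.dlam == 0 or self.s == 0):
            raise ValueError("all-zero generative model: no GO evidence possible")

    @property
    def dist(self) -> tuple[float, ...]:
        if self.cardinality_dist is not None:
            return self.cardinality_dist
        return default_cardinality_dist(self.c)

    @property
    def label_names(self) -> tuple[str, ...]:
        if self.c <= len(COMPARTMENTS):
            return COMPARTMENTS[: self.c]
        extras = tuple(
            f"location{i:02d}" for i in range(len(COMPARTMENTS), self.c)
        )
        return COMPARTMENTS + extras


@dataclass
class SyntheticTruth:
    """A generated cohort together with its ground truth.

    ``annotation_map`` and ``homolog_map`` mirror the fixture files
    written by :func:`write_fixtures`: each protein SPxxxxx has one
    synthetic homolog HMxxxxx whose GAF rows encode the protein's
    term counts, so the encoding pipeline (max_homologs >= 1)
    reconstructs ``dataset.X`` exactly.
    """

    config: SyntheticConfig
    dataset: MultiLabelDataset
    signal_indices: list[np.ndarray]
    annotation_map: GOAnnotationTable
    homolog_map: HomologSet

    @property
    def signal_terms(self) -> list[tuple[str, ...]]:
        terms = self.dataset.subspace.terms
        return [tuple(terms[j] for j in idx) for idx in self.signal_indices]


def _term_id(j: int) -> str:
    # zero-padded, so lexicographic term order equals column order
    return f"GO:{j + 1:07d}"


def generate(config: SyntheticConfig) -> SyntheticTruth:
    """Draw a synthetic cohort fully determined by ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n, c, omega, s = config.n, config.c, config.omega, config.s
    dist = np.asarray(config.dist)
    sizes = np.arange(1, dist.size + 1)

    # planted signal columns: label i owns columns [i*s, (i+1)*s)
    signal_columns = [np.arange(i * s, (i + 1) * s) for i in range(c)]

    Y = -np.ones((n, c), dtype=np.int64)
    X = np.zeros((n, omega), dtype=np.int64)
    for k in range(n):
        cardinality = int(rng.choice(sizes, p=dist))
        held = rng.choice(c, size=cardinality, replace=False)
        Y[k, held] = 1
        for _ in range(1000):
            row = rng.poisson(config.lam0, omega)
            for i in held:
                row[signal_columns[i]] += rng.poisson(config.dlam, s)
            if row.sum() > 0:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a nonzero feature row")
        X[k] = row

    # drop never-observed terms so the subspace matches what parsing the
    # fixtures would reconstruct; remap planted indices accordingly
    observed = np.flatnonzero(X.sum(axis=0) > 0)
    position = {int(j): p for p, j in enumerate(observed)}
    X = X[:, observed]
    subspace = GOSubspace(_term_id(int(j)) for j in observed)
    signal_indices = [
        np.array([position[int(j)] for j in cols if int(j) in position])
        for cols in signal_columns
    ]

    accessions = [f"SP{k:05d}" for k in range(n)]
    labelspace = LabelSpace(config.label_names)
    dataset = MultiLabelDataset(accessions, X, Y, subspace, labelspace)

    annotation: dict[str, Counter] = {}
    homologs: dict[str, list[BlastHit]] = {}
    for k, accession in enumerate(accessions):
        homolog = f"HM{k:05d}"
        counts = Counter(
            {subspace.terms[j]: int(X[k, j]) for j in np.flatnonzero(X[k])}
        )
        annotation[homolog] = counts
        homologs[accession] = [BlastHit(homolog, 1e-50, 200.0)]

    return SyntheticTruth(
        config=config,
        dataset=dataset,
        signal_indices=signal_indices,
        annotation_map=GOAnnotationTable(annotation),
        homolog_map=HomologSet(homologs),
    )


_GAF_TEMPLATE = (
    "SYN\t{acc}\t{acc}\t\t{term}\tSYN_REF:0000001\tIEA\t\tC\t\t\t"
    "protein\ttaxon:9606\t20160704\tSYN\t\t\n"
)


def write_fixtures(truth: SyntheticTruth, out_dir: str | Path) -> dict[str, Path]:
    """Write GAF / BLAST tabular / labels TSV / truth JSON fixture files.

    Each protein's counts are expressed as repeated GAF annotation rows
    on its synthetic homolog accession; the BLAST file links protein to
    homolog at e-value 1e−50. Parsing the files back through the
    encoding pipeline reproduces ``truth.dataset.X`` exactly.
    """
    dataset = truth.dataset
    if dataset.n == 0:
        raise ValueError("refusing to write fixtures for an empty dataset")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gaf": out_dir / "annotations.gaf",
        "blast": out_dir / "homologs.blast.tsv",
        "labels": out_dir / "labels.tsv",
        "truth": out_dir / "truth.json",
    }

    with open(paths["gaf"], "w", encoding="utf-8") as handle:
        handle.write("!gaf-version: 2.1\n")
        for accession in truth.annotation_map.accessions():
            counts = truth.annotation_map.terms_for(accession)
            for term in sorted(counts):
                for _ in range(counts[term]):
                    handle.write(_GAF_TEMPLATE.format(acc=accession, term=term))

    with open(paths["blast"], "w", encoding="utf-8") as handle:
        for query in truth.homolog_map.queries():
            for hit in truth.homolog_map.hits_for(query):
                handle.write(
                    f"{query}\t{hit.subject}\t100.000\t100\t0\t0\t1\t100\t1\t100"
                    f"\t{hit.evalue:.2e}\t{hit.bitscore:.1f}\n"
                )

    write_labels_tsv(
        {
            accession: sorted(dataset.label_set(k))
            for k, accession in enumerate(dataset.accessions)
        },
        paths["labels"],
    )

    with open(paths["truth"], "w", encoding="utf-8") as handle:
        json.dump(
            {
                "config": {
                    "n": truth.config.n,
                    "c": truth.config.c,
                    "omega": truth.config.omega,
                    "s": truth.config.s,
                    "lam0": truth.config.lam0,
                    "dlam": truth.config.dlam,
                    "cardinality_dist": list(truth.config.dist),
                    "seed": truth.config.seed,
                },
                "labels": list(dataset.labelspace.labels),
                "observed_omega": dataset.omega,
                "signal_terms": [list(t) for t in truth.signal_terms],
            },
            handle,
            indent=1,
        )
    return paths
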