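"""Genomic data types and interval arithmetic.

Coordinates are 1-based and fully inclusive everywhere in the public API,
matching the locus notation used throughout the workflow (``ECA29:
21,894,122-21,902,694`` is 8,573 bp long).  Any half-open representation used
internally (e.g. by the interval index) never leaks across an interface.

Distance between two intervals on the same chromosome is the count of bases
strictly between them: overlapping or directly abutting intervals are at
distance 0, ``[1,10]`` and ``[21,30]`` are 10 bases apart (bases 11-20).
Strand is carried on every interval but deliberately ignored for overlap and
distance queries: the intergenic-distance filter of the triage cascade is
strand-blind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")

#: sentinel returned when two intervals cannot be compared (different chromosomes)
INFINITE_DISTANCE = math.inf


class NovtxError(Exception):
    """Base class for every error raised by this package."""


class ParseError(NovtxError):
    """A malformed record in an input file.

    Carries enough context (source name, line number) to point at the
    offending record.
    """

    def __init__(self, message: str, source: str | None = None, line: int | None = None):
        self.source = source
        self.line = line
        prefix = ""
        if source is not None:
            prefix = f"{source}:" + (f"{line}: " if line is not None else " ")
        super().__init__(prefix + message)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed interval ``[start, end]`` on one chromosome (1-based)."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # locus notation
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Bases strictly between ``a`` and ``b``; 0 on overlap or abutment.

    Different chromosomes are infinitely far apart
    (:data:`INFINITE_DISTANCE`).
    """
    if a.chrom != b.chrom:
        return INFINITE_DISTANCE
    gap = max(a.start, b.start) - min(a.end, b.end) - 1
    return float(max(0, gap))


@dataclass
class TranscriptModel:
    """One putative transcript: exon structure plus read-level evidence.

    ``depth`` is a single scalar per model (the minimum read coverage across
    its exons, supplied by the evidence sidecar).  ``junction_support`` lists
    (intron interval, spanning-read count) pairs.
    """

    id: str
    exons: list[GenomicInterval]
    depth: float = 0.0
    junction_support: list[tuple[GenomicInterval, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id}: at least one exon required")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(
                f"transcript {self.id}: exons span multiple chromosomes {sorted(chroms)}"
            )
        strands = {e.strand for e in self.exons}
        if len(strands) > 1:
            raise ValueError(f"transcript {self.id}: exons on multiple strands")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start <= prev.end:
                raise ValueError(
                    f"transcript {self.id}: overlapping exons {prev} and {nxt}"
                )
        if self.depth < 0:
            raise ValueError(f"transcript {self.id}: negative depth {self.depth}")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        return genomic_span(self)

    @property
    def introns(self) -> list[GenomicInterval]:
        out = []
        for prev, nxt in zip(self.exons, self.exons[1:]):
            if nxt.start - prev.end >= 2:
                out.append(
                    GenomicInterval(self.chrom, prev.end + 1, nxt.start - 1, self.strand)
                )
        return out


def genomic_span(model: TranscriptModel) -> GenomicInterval:
    """Locus of the model: first exon start to last exon end."""
    return GenomicInterval(
        model.chrom, model.exons[0].start, model.exons[-1].end, model.strand
    )


@dataclass(frozen=True)
class AnnotationFeature:
    """A gene or pseudogene record from the reference annotation."""

    id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"


class AnnotationSet:
    """Indexed collection of annotated genes/pseudogenes.

    Backed by one interval tree per chromosome for overlap queries; the
    novelty screen and the intergenic-distance filter both run against it.
    """

    def __init__(self, features: Iterable[AnnotationFeature] = ()):
        self._features: dict[str, AnnotationFeature] = {}
        self._trees: dict[str, IntervalTree] = {}
        self._by_chrom: dict[str, list[AnnotationFeature]] = {}
        for feat in features:
            self.add(feat)

    def add(self, feat: AnnotationFeature) -> None:
        if feat.id in self._features:
            raise ValueError(f"duplicate feature id {feat.id!r}")
        self._features[feat.id] = feat
        iv = feat.interval
        # interval tree is half-open; +1 keeps the closed-coordinate contract
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, feat)
        self._by_chrom.setdefault(iv.chrom, []).append(feat)

    def __len__(self) -> int:
        return len(self._features)

    def __iter__(self) -> Iterator[AnnotationFeature]:
        return iter(self._features.values())

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._features

    def __getitem__(self, feature_id: str) -> AnnotationFeature:
        return self._features[feature_id]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    def features_on(self, chrom: str) -> list[AnnotationFeature]:
        return sorted(self._by_chrom.get(chrom, []), key=lambda f: f.interval.start)

    def overlapping(self, query: GenomicInterval) -> list[AnnotationFeature]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        hits = tree.overlap(query.start, query.end + 1)
        return sorted((h.data for h in hits), key=lambda f: f.interval.start)

    def nearest_distance(self, query: GenomicInterval) -> float:
        """Distance to the closest feature on the query's chromosome.

        Returns :data:`INFINITE_DISTANCE` when the chromosome carries no
        annotation at all.
        """
        feats = self._by_chrom.get(query.chrom)
        if not feats:
            return INFINITE_DISTANCE
        if self._trees[query.chrom].overlaps(query.start, query.end + 1):
            return 0.0
        return min(interval_distance(query, f.interval) for f in feats)


def overlaps_annotation(model: TranscriptModel, ann: AnnotationSet) -> bool:
    """True iff any exon shares >= 1 base with any annotated feature."""
    return any(ann.overlapping(exon) for exon in model.exons)


@dataclass
class ExpressionRow:
    """Normalized expression of one transcript across N tissues."""

    transcript_id: str
    values: list[float]
    tissue_names: list[str]

    def __post_init__(self) -> None:
        if len(self.values) != len(self.tissue_names):
            raise ValueError(
                f"{self.transcript_id}: {len(self.values)} values for "
                f"{len(self.tissue_names)} tissues"
            )
        if any(v < 0 for v in self.values):
            raise ValueError(f"{self.transcript_id}: negative expression value")

    @property
    def n_tissues(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class HomologyHit:
    """One tabular homology-search alignment record.

    ``subject_is_annotated_gene`` is an input column: whether the subject
    sequence is annotated as a transcribed gene is decided upstream, not
    inferred here.
    """

    query_id: str
    subject_id: str
    evalue: float
    bitscore: float
    subject_is_annotated_gene: bool
    subject_description: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.evalue) or self.evalue < 0:
            raise ValueError(f"{self.query_id}: bad e-value {self.evalue}")
        if not math.isfinite(self.bitscore) or self.bitscore < 0:
            raise ValueError(f"{self.query_id}: bad bit score {self.bitscore}")


def sort_models(models: Sequence[TranscriptModel]) -> list[TranscriptModel]:
    return sorted(models, key=lambda m: (m.chrom, m.exons[0].start, m.id))
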