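"""Shared genomic data model.

All coordinates are 0-based half-open (BED convention); conversion to and
from the 1-based inclusive GTF convention happens only at the I/O boundary
(:mod:`adipolnc.io_formats`). Strand is mandatory everywhere: the filter
cascade, novelty calls and synteny contexts are all strand-aware, so
unstranded records are rejected at construction time rather than guessed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

STRANDS = ("+", "-")

BIOTYPES = ("protein_coding", "reference_lncRNA", "candidate")
NOVELTY = ("novel", "annotated", "unset")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = True) -> bool:
        """True iff >=1 bp shared (and same strand when ``stranded``)."""
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def gap_to(self, other: "GenomicInterval") -> int:
        """Span-to-span distance in bp; 0 when the spans overlap or touch."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(self.start - other.end, other.start - self.end, 0)


@dataclass
class TranscriptModel:
    """A stranded multi-exon transcript with per-sample coverage/FPKM.

    The unit flowing through the filter cascade. ``coverage`` and ``fpkm``
    are keyed by sample (tissue) name; absent keys mean the transcript was
    not assembled in that sample and downstream filters treat the value as 0.
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "candidate"
    coverage: dict[str, float] = field(default_factory=dict)
    fpkm: dict[str, float] = field(default_factory=dict)
    novelty: str = "unset"

    def __post_init__(self) -> None:
        self.exons = tuple(sorted(self.exons, key=lambda e: e.start))
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >=1 exon")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"{self.transcript_id}: exons must share one chrom and strand"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if self.novelty not in NOVELTY:
            raise ValueError(f"unknown novelty {self.novelty!r}")
        for name, table in (("coverage", self.coverage), ("fpkm", self.fpkm)):
            for k, v in table.items():
                if v < 0:
                    raise ValueError(f"{self.transcript_id}: negative {name}[{k}]")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    def intron_chain_key(self) -> tuple:
        """Identity used to unify transcripts across per-tissue assemblies.

        Multi-exon transcripts match on their ordered intron coordinates;
        single-exon transcripts only on their exact exon span.
        """
        if self.n_exons >= 2:
            return (self.chrom, self.strand, "introns", self.introns)
        e = self.exons[0]
        return (self.chrom, self.strand, "single", e.start, e.end)


@dataclass
class GeneRecord:
    """A gene locus: the span covering all of its transcripts."""

    gene_id: str
    span: GenomicInterval
    biotype: str = "candidate"

    def __post_init__(self) -> None:
        if self.biotype not in BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start, 0-based."""
        return self.span.start if self.span.strand == "+" else self.span.end - 1


def genes_from_transcripts(
    transcripts: Iterable[TranscriptModel], default_biotype: str | None = None
) -> list[GeneRecord]:
    """Collapse transcripts into gene records (span = union of transcript spans)."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    out = []
    for gid, ts in by_gene.items():
        chroms = {t.chrom for t in ts}
        strands = {t.strand for t in ts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"gene {gid}: transcripts on multiple chroms/strands")
        span = GenomicInterval(
            ts[0].chrom,
            min(t.span.start for t in ts),
            max(t.span.end for t in ts),
            ts[0].strand,
        )
        out.append(GeneRecord(gid, span, default_biotype or ts[0].biotype))
    return out


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT content) plus an optional explicit universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")


class OrthologMap:
    """One-to-one cross-species coding-gene correspondence.

    Many-to-many input rows are resolved by keeping the first-listed pair
    per gene; the number of discarded rows is kept for logging.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.a2b: dict[str, str] = {}
        self.b2a: dict[str, str] = {}
        self.n_discarded = 0
        for a, b in pairs:
            if a in self.a2b or b in self.b2a:
                self.n_discarded += 1
                continue
            self.a2b[a] = b
            self.b2a[b] = a

    def __len__(self) -> int:
        return len(self.a2b)

    def to_b(self, gene_a: str) -> str | None:
        return self.a2b.get(gene_a)

    def to_a(self, gene_b: str) -> str | None:
        return self.b2a.get(gene_b)


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM table with an mRNA/lncRNA class label per gene."""

    values: pd.DataFrame
    classes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.values.isna().any().any():
            raise ValueError("missing expression cells are not allowed")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative FPKM values are not allowed")
        if self.classes is not None:
            self.classes = self.classes.reindex(self.values.index)
            bad = set(self.classes.dropna().unique()) - {"mRNA", "lncRNA"}
            if bad:
                raise ValueError(f"unknown gene classes: {sorted(bad)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def of_class(self, cls: str) -> "ExpressionMatrix":
        if self.classes is None:
            raise ValueError("matrix carries no class labels")
        keep = self.classes[self.classes == cls].index
        return ExpressionMatrix(self.values.loc[keep], self.classes.loc[keep])

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        cls = self.classes.loc[genes] if self.classes is not None else None
        return ExpressionMatrix(self.values.loc[genes], cls)
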