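"""The lncRNA catalog builder.

Turns assembled candidate transcripts into a lncRNA catalog through five
conjunctive filters — read coverage >= 3 in at least one tissue, length
>= 200 bp, >= 2 exons, low coding potential (precomputed PhyloCSF-style
score <= 0), and no same-strand exonic overlap with known coding genes —
then splits the survivors into novel vs annotated against a reference
lncRNA annotation.

Coding potential is consumed as a precomputed per-transcript score table
(higher = more coding-like); :func:`longest_orf` is provided as an
auxiliary descriptor and optional fallback filter (off by default).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import TranscriptModel

log = logging.getLogger(__name__)

FILTER_NAMES = ("coverage", "length", "exons", "coding_potential", "sense_overlap")


@dataclass
class FilterConfig:
    """Thresholds of the five-criterion filter cascade (all boundaries inclusive)."""

    min_coverage: float = 3.0
    min_length_bp: int = 200
    min_exons: int = 2
    coding_score_max: float = 0.0
    missing_score_policy: str = "error"  # or "noncoding"
    orf_filter_max_nt: int | None = None  # optional auxiliary ORF-length filter

    def __post_init__(self) -> None:
        if self.min_length_bp < 1 or self.min_exons < 1 or self.min_coverage < 0:
            raise ValueError("invalid filter thresholds")
        if self.missing_score_policy not in ("error", "noncoding"):
            raise ValueError("missing_score_policy must be 'error' or 'noncoding'")


def transcript_length(t: TranscriptModel) -> int:
    """Mature transcript length: sum of exon lengths in bp."""
    return sum(e.end - e.start for e in t.exons)


class ExonOverlapIndex:
    """Strand-aware interval index over the union of exons of an annotation set."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for t in transcripts:
            for e in t.exons:
                self._trees.setdefault((e.chrom, e.strand), IntervalTree()).addi(
                    e.start, e.end
                )
        self._warned: set[str] = set()

    def overlaps(self, t: TranscriptModel) -> bool:
        """True iff >=1 bp of any exon of ``t`` hits an indexed exon on the
        same chrom and strand. Intronic overlap does not count."""
        tree = self._trees.get((t.chrom, t.strand))
        if tree is None:
            if t.chrom not in self._warned:
                self._warned.add(t.chrom)
                log.info("chromosome %s absent from overlap index", t.chrom)
            return False
        return any(tree.overlaps(e.start, e.end) for e in t.exons)


def sense_overlaps_coding(t: TranscriptModel, index: ExonOverlapIndex) -> bool:
    return index.overlaps(t)


_STOPS = frozenset({"TAA", "TAG", "TGA"})
_ALPHABET = frozenset("ACGTN")


def longest_orf(sequence: str) -> int:
    """Length in nt of the longest ATG..stop open reading frame (stop included).

    Scans all three sense frames only (the libraries are strand-specific);
    returns 0 when no complete ORF exists.
    """
    seq = sequence.upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    best = 0
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if start is None:
                if codon == "ATG":
                    start = i
            elif codon in _STOPS:
                best = max(best, i + 3 - start)
                start = None
    return best


def match_by_intron_chain(
    assemblies: Mapping[str, Sequence[TranscriptModel]]
) -> list[TranscriptModel]:
    """Unify per-tissue assemblies into one transcript set.

    Transcripts with identical ordered intron coordinates (chrom, strand,
    all intron start/end pairs) are the same molecule assembled in several
    tissues; their coverage/FPKM are merged keyed by tissue. Single-exon
    transcripts match only on their identical exon span. The representative
    exon structure and transcript_id come from the first tissue (in mapping
    order) where the chain was seen.
    """
    unified: dict[tuple, TranscriptModel] = {}
    for tissue, transcripts in assemblies.items():
        for t in transcripts:
            key = t.intron_chain_key()
            if key not in unified:
                unified[key] = TranscriptModel(
                    transcript_id=t.transcript_id,
                    gene_id=t.gene_id,
                    exons=t.exons,
                    biotype=t.biotype,
                    coverage=dict(t.coverage),
                    fpkm=dict(t.fpkm),
                )
            else:
                u = unified[key]
                u.coverage.update(t.coverage)
                u.fpkm.update(t.fpkm)
    return list(unified.values())


@dataclass
class CatalogReport:
    """Per-stage bookkeeping of the filter cascade.

    ``stages`` telescopes: each stage's output count equals the next
    stage's input count; ``fates`` names the first filter that removed each
    rejected transcript (the filters are conjunctive, so the final catalog
    is order-invariant even though attribution follows cascade order).
    """

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    fates: dict[str, str] = field(default_factory=dict)
    n_input: int = 0
    n_final: int = 0
    n_novel: int = 0
    n_annotated: int = 0

    @property
    def removals(self) -> dict[str, int]:
        return {name: n_in - n_out for name, n_in, n_out in self.stages}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"stage": name, "n_in": n_in, "n_out": n_out, "removed": n_in - n_out}
            for name, n_in, n_out in self.stages
        ]
        rows.append(
            {
                "stage": "final",
                "n_in": self.n_final,
                "n_out": self.n_final,
                "removed": 0,
            }
        )
        return pd.DataFrame(rows)


def _passes(
    t: TranscriptModel,
    name: str,
    cfg: FilterConfig,
    scores: Mapping[str, float],
    coding_index: ExonOverlapIndex,
) -> bool:
    if name == "coverage":
        # missing tissue coverage is 0, not missing-data
        return any(v >= cfg.min_coverage for v in t.coverage.values())
    if name == "length":
        return transcript_length(t) >= cfg.min_length_bp
    if name == "exons":
        return t.n_exons >= cfg.min_exons
    if name == "coding_potential":
        if t.transcript_id not in scores:
            if cfg.missing_score_policy == "error":
                raise KeyError(
                    f"no coding score for {t.transcript_id} "
                    "(set missing_score_policy='noncoding' to keep such models)"
                )
            return True
        return scores[t.transcript_id] <= cfg.coding_score_max
    if name == "sense_overlap":
        return not sense_overlaps_coding(t, coding_index)
    raise ValueError(f"unknown filter {name!r}")


def build_catalog(
    transcripts: Sequence[TranscriptModel],
    config: FilterConfig,
    scores: Mapping[str, float],
    coding_annotation: Sequence[TranscriptModel],
    reference_lnc: Sequence[TranscriptModel] = (),
    filter_order: Sequence[str] = FILTER_NAMES,
) -> tuple[list[TranscriptModel], CatalogReport]:
    """Apply the five filters conjunctively and label survivor novelty.

    Novelty: ``annotated`` iff >=1 bp same-strand exonic overlap with the
    reference lncRNA annotation, else ``novel``.
    """
    if sorted(filter_order) != sorted(FILTER_NAMES):
        raise ValueError("filter_order must be a permutation of the five filters")
    coding_index = ExonOverlapIndex(coding_annotation)
    ref_index = ExonOverlapIndex(reference_lnc)

    report = CatalogReport(n_input=len(transcripts))
    surviving = list(transcripts)
    for name in filter_order:
        n_in = len(surviving)
        kept = []
        for t in surviving:
            if _passes(t, name, config, scores, coding_index):
                kept.append(t)
            else:
                report.fates[t.transcript_id] = name
        surviving = kept
        report.stages.append((name, n_in, len(surviving)))

    if config.orf_filter_max_nt is not None:
        raise NotImplementedError(
            "ORF-length fallback filtering requires sequences; "
            "use longest_orf() directly"
        )

    catalog = []
    for t in surviving:
        novelty = "annotated" if ref_index.overlaps(t) else "novel"
        catalog.append(
            TranscriptModel(
                transcript_id=t.transcript_id,
                gene_id=t.gene_id,
                exons=t.exons,
                biotype=t.biotype,
                coverage=dict(t.coverage),
                fpkm=dict(t.fpkm),
                novelty=novelty,
            )
        )
    report.n_final = len(catalog)
    report.n_novel = sum(1 for t in catalog if t.novelty == "novel")
    report.n_annotated = report.n_final - report.n_novel
    return catalog, report
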