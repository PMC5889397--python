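"""Readers and writers for the external formats the pipeline touches.

GTF (plain and Cufflinks attribute dialects), BED6/BED12, TSV expression /
coverage / score / ortholog tables and GMT gene sets. All coordinates are
converted to 0-based half-open on read and back to 1-based inclusive GTF on
write; all writers emit UTF-8, tab-delimited, LF line endings.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

from .model import (
    ExpressionMatrix,
    GeneRecord,
    GeneSetCollection,
    GenomicInterval,
    OrthologMap,
    TranscriptModel,
    genes_from_transcripts,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(
    path: str | Path,
    attribute_dialect: str = "plain",
    sample: str | None = None,
    default_biotype: str = "candidate",
) -> tuple[list[TranscriptModel], list[GeneRecord]]:
    """Read exon features from a GTF file into transcript and gene models.

    Parameters
    ----------
    attribute_dialect
        ``"cufflinks"`` additionally parses per-transcript ``cov`` and
        ``FPKM`` attributes, stored under the caller-supplied ``sample`` name.
    sample
        Sample/tissue name under which cov/FPKM are keyed (cufflinks dialect).

    Single-exon transcripts are retained here; filtering is downstream.
    """
    if attribute_dialect not in ("plain", "cufflinks"):
        raise ValueError(f"unknown attribute dialect {attribute_dialect!r}")
    if attribute_dialect == "cufflinks" and sample is None:
        raise ValueError("cufflinks dialect requires a sample name")

    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # gffutils raises assorted types
                raise ParseError(f"{path}: malformed GTF line {lineno}: {exc}")
            if feat.featuretype != "exon":
                continue
            if feat.strand not in ("+", "-"):
                raise ParseError(
                    f"{path}: line {lineno}: unstranded exon rejected "
                    "(every downstream filter is strand-aware)"
                )
            if feat.end < feat.start:
                raise ParseError(
                    f"{path}: line {lineno}: exon end < start rejected"
                )
            attrs = feat.attributes
            if "transcript_id" not in attrs:
                raise ParseError(f"{path}: line {lineno}: missing transcript_id")
            tid = attrs["transcript_id"][0]
            # GTF is 1-based inclusive -> 0-based half-open
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
            exons.setdefault(tid, []).append(iv)
            if tid not in meta:
                gid = attrs["gene_id"][0] if "gene_id" in attrs else tid
                biotype = (
                    attrs["gene_biotype"][0]
                    if "gene_biotype" in attrs
                    else default_biotype
                )
                coverage: dict[str, float] = {}
                fpkm: dict[str, float] = {}
                if attribute_dialect == "cufflinks":
                    if "cov" in attrs:
                        coverage[sample] = float(attrs["cov"][0])
                    if "FPKM" in attrs:
                        fpkm[sample] = float(attrs["FPKM"][0])
                meta[tid] = dict(
                    gene_id=gid, biotype=biotype, coverage=coverage, fpkm=fpkm
                )

    transcripts = [
        TranscriptModel(transcript_id=tid, exons=tuple(ivs), **meta[tid])
        for tid, ivs in exons.items()
    ]
    genes = genes_from_transcripts(transcripts)
    return transcripts, genes


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    sample: str | None = None,
    source: str = "adipolnc",
) -> None:
    """Write exon lines in 1-based inclusive GTF; cov/FPKM for ``sample`` if given."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for t in transcripts:
            for exon in t.exons:
                attrs = [
                    f'gene_id "{t.gene_id}"',
                    f'transcript_id "{t.transcript_id}"',
                    f'gene_biotype "{t.biotype}"',
                ]
                if sample is not None:
                    if sample in t.coverage:
                        attrs.append(f'cov "{t.coverage[sample]!r}"')
                    if sample in t.fpkm:
                        attrs.append(f'FPKM "{t.fpkm[sample]!r}"')
                fh.write(
                    "\t".join(
                        [
                            exon.chrom,
                            source,
                            "exon",
                            str(exon.start + 1),
                            str(exon.end),
                            ".",
                            exon.strand,
                            ".",
                            "; ".join(attrs) + ";",
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Expression / coverage / score / ortholog tables
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path, classes: pd.Series | None = None
) -> ExpressionMatrix:
    """Read a genes x samples FPKM TSV (first column gene_id, header = samples)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene id in expression matrix")
    if df.isna().any().any():
        raise ValueError(f"{path}: missing cells are not allowed")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression cell: {exc}")
    if (df.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression value")
    return ExpressionMatrix(df, classes)


def write_expression_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


def read_class_table(path: str | Path) -> pd.Series:
    """Two-column TSV (gene_id, class in {mRNA, lncRNA}) -> Series."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="class")


def read_score_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV (transcript_id, coding-potential score) -> mapping."""
    out: dict[str, float] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or lineno == 1 and not _is_row(line):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            out[fields[0]] = float(fields[1])
    return out


def _is_row(line: str) -> bool:
    fields = line.split("\t")
    if len(fields) < 2:
        return False
    try:
        float(fields[1])
        return True
    except ValueError:
        return False


def read_coverage_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Coverage TSV keyed by transcript_id with one column per tissue."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return {tid: row.astype(float).to_dict() for tid, row in df.iterrows()}


def read_ortholog_table(
    path: str | Path,
    known_a: set[str] | None = None,
    known_b: set[str] | None = None,
) -> OrthologMap:
    """Two-column TSV (speciesA_gene, speciesB_gene) -> OrthologMap.

    Rows referencing gene ids absent from the supplied known sets are
    skipped with a logged count.
    """
    pairs: list[tuple[str, str]] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 columns")
            a, b = fields[0], fields[1]
            if (known_a is not None and a not in known_a) or (
                known_b is not None and b not in known_b
            ):
                skipped += 1
                continue
            pairs.append((a, b))
    if skipped:
        log.warning("%s: skipped %d ortholog rows with unknown gene ids", path, skipped)
    return OrthologMap(pairs)


def write_ortholog_table(orth: OrthologMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in orth.a2b.items():
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """One gene set per line: name, description, then members (tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT line needs >=3 fields"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}: line {lineno}: duplicate set {name!r}")
            sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(
    transcripts: Iterable[TranscriptModel], path: str | Path, bed12: bool = True
) -> None:
    """Write the catalog as BED6, or blocked BED12 for multi-exon models."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for t in transcripts:
            span = t.span
            base = [span.chrom, str(span.start), str(span.end), t.transcript_id,
                    "0", span.strand]
            if not bed12:
                fh.write("\t".join(base) + "\n")
                continue
            sizes = ",".join(str(e.length) for e in t.exons)
            starts = ",".join(str(e.start - span.start) for e in t.exons)
            fh.write(
                "\t".join(
                    base
                    + [str(span.start), str(span.end), "0",
                       str(t.n_exons), sizes, starts]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA and generic TSV reports
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_tsv_report(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n")
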