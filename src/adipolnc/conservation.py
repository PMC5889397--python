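"""Synteny-based cross-species lncRNA ortholog calling.

Most lncRNAs lack detectable sequence homology between human and mouse, so
orthology is inferred positionally: a lncRNA in species A is called
conserved when some species-B lncRNA sits in an equivalent neighbourhood —
the protein-coding genes within +/-500 kb on the lncRNA's strand, mapped
through a coding-gene ortholog table, appear in the same relative order
around both lncRNAs. An externally computed sequence-similarity pair table
can be merged in ("either criterion" calls conservation).

lncRNAs in gene deserts (no same-strand coding gene within the window)
yield empty contexts and are unresolvable by synteny.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import GeneRecord, OrthologMap

log = logging.getLogger(__name__)

LNC_TOKEN = "__LNC__"


@dataclass
class SyntenyContext:
    """Ordered same-strand coding-gene neighbourhood of one lncRNA.

    ``flanking`` holds (gene_id, signed span-gap offset, strand) sorted by
    chromosomal position; negative offsets are genomically left of the
    lncRNA, 0 means the spans overlap.
    """

    lnc_id: str
    strand: str
    window_bp: int
    flanking: tuple[tuple[str, int, str], ...]

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _, _ in self.flanking)

    @property
    def is_desert(self) -> bool:
        return not self.flanking

    def ordered_tokens(self, restrict: set[str] | None = None) -> list[str]:
        """Gene ids in chromosomal order with the lncRNA inserted at its
        position; optionally restricted to a shared-gene subset."""
        tokens: list[str] = []
        placed = False
        for gid, off, _ in self.flanking:
            if off >= 0 and not placed:
                tokens.append(LNC_TOKEN)
                placed = True
            if restrict is None or gid in restrict:
                tokens.append(gid)
        if not placed:
            tokens.append(LNC_TOKEN)
        return tokens


@dataclass
class ConservationCall:
    lnc_id: str
    partner: str | None
    evidence: str  # "synteny", "sequence" or "both"
    shared_flanking: int

    def __post_init__(self) -> None:
        if self.partner is not None and self.evidence not in (
            "synteny",
            "sequence",
            "both",
        ):
            raise ValueError("evidence required when a partner is present")


def build_context(
    lnc: GeneRecord, genes: Iterable[GeneRecord], window_bp: int = 500_000
) -> SyntenyContext:
    """Collect protein-coding genes within +/-window of the lncRNA span, on
    its chromosome and strand. The window is inclusive: a gene whose span
    gap to the lncRNA equals the window is in; overlapping genes count with
    offset 0."""
    flank: list[tuple[int, str, int, str]] = []  # (sort pos, id, offset, strand)
    for g in genes:
        if g.biotype != "protein_coding":
            continue
        if g.span.chrom != lnc.span.chrom or g.span.strand != lnc.span.strand:
            continue
        gap = g.span.gap_to(lnc.span)
        if gap > window_bp:
            continue
        if g.span.end <= lnc.span.start:
            offset = g.span.end - lnc.span.start  # negative, upstream in coords
        elif g.span.start >= lnc.span.end:
            offset = g.span.start - lnc.span.end
        else:
            offset = 0
        flank.append((g.span.start, g.gene_id, offset, g.span.strand))
    flank.sort()
    return SyntenyContext(
        lnc_id=lnc.gene_id,
        strand=lnc.span.strand,
        window_bp=window_bp,
        flanking=tuple((gid, off, s) for _, gid, off, s in flank),
    )


def synteny_match(
    ctx_a: SyntenyContext,
    ctx_b: SyntenyContext,
    orth: OrthologMap,
    min_shared: int = 2,
    allow_inversion: bool = True,
    require_sidedness: bool = True,
) -> tuple[bool, int]:
    """Test whether two lncRNA neighbourhoods are syntenic.

    Each context is restricted to coding genes whose ortholog appears in
    the other context; the match requires (a) at least ``min_shared`` such
    genes (one gene cannot establish relative order), (b) identical shared
    gene order read along the chromosome with the lncRNA inserted at its
    position, and (c) preserved upstream/downstream sidedness. When the two
    lncRNAs sit on opposite assembly strands and ``allow_inversion`` is on,
    the species-B context is also compared after whole-context reversal
    (synteny blocks invert between assemblies).
    """
    b_ids = set(ctx_b.gene_ids)
    shared_a = {
        gid for gid in ctx_a.gene_ids if orth.to_b(gid) is not None
        and orth.to_b(gid) in b_ids
    }
    shared_b = {orth.to_b(gid) for gid in shared_a}
    n_shared = len(shared_a)
    if n_shared < min_shared:
        return False, n_shared

    tokens_a = [
        orth.to_b(t) if t != LNC_TOKEN else LNC_TOKEN
        for t in ctx_a.ordered_tokens(restrict=shared_a)
    ]
    tokens_b = ctx_b.ordered_tokens(restrict=shared_b)
    if not require_sidedness:
        tokens_a = [t for t in tokens_a if t != LNC_TOKEN]
        tokens_b = [t for t in tokens_b if t != LNC_TOKEN]
    if tokens_a == tokens_b:
        return True, n_shared
    if allow_inversion and ctx_a.strand != ctx_b.strand:
        if tokens_a == tokens_b[::-1]:
            return True, n_shared
    return False, n_shared


def _nearest_offset(ctx: SyntenyContext, shared: set[str]) -> int:
    offs = [abs(off) for gid, off, _ in ctx.flanking if gid in shared]
    return min(offs) if offs else 0


def conserved_catalog(
    lnc_a: Sequence[GeneRecord],
    lnc_b: Sequence[GeneRecord],
    genes_a: Sequence[GeneRecord],
    genes_b: Sequence[GeneRecord],
    orth: OrthologMap,
    window_bp: int = 500_000,
    min_shared: int = 2,
    similarity_hits: Iterable[tuple[str, str]] | None = None,
    allow_inversion: bool = True,
    require_sidedness: bool = True,
) -> list[ConservationCall]:
    """Call conservation for every species-A lncRNA.

    A lncRNA is conserved iff synteny matches >=1 species-B lncRNA OR it
    appears in the sequence-similarity table. At most one call per lncRNA:
    the syntenic partner sharing the most flanking orthologs wins, ties
    broken by the smallest nearest-shared-flank offset discrepancy, then by
    partner id (logged).
    """
    ctxs_b = [build_context(l, genes_b, window_bp) for l in lnc_b]
    known_a = {l.gene_id for l in lnc_a}
    known_b = {l.gene_id for l in lnc_b}
    sim: dict[str, str] = {}
    for a, b in similarity_hits or ():
        if a not in known_a or b not in known_b:
            log.warning("similarity hit (%s, %s) references unknown lncRNA; skipped", a, b)
            continue
        sim.setdefault(a, b)

    calls: list[ConservationCall] = []
    for l in lnc_a:
        ctx_a = build_context(l, genes_a, window_bp)
        best: tuple[int, int, str] | None = None  # (-shared, discrepancy, partner)
        for ctx_b in ctxs_b:
            ok, shared = synteny_match(
                ctx_a, ctx_b, orth, min_shared, allow_inversion, require_sidedness
            )
            if not ok:
                continue
            shared_a_ids = {
                gid
                for gid in ctx_a.gene_ids
                if orth.to_b(gid) in set(ctx_b.gene_ids)
            }
            shared_b_ids = {orth.to_b(g) for g in shared_a_ids}
            disc = abs(
                _nearest_offset(ctx_a, shared_a_ids)
                - _nearest_offset(ctx_b, shared_b_ids)
            )
            cand = (-shared, disc, ctx_b.lnc_id)
            if best is None or cand < best:
                if best is not None and cand[:2] == best[:2]:
                    log.info("tie for %s broken by partner id", l.gene_id)
                best = cand
        if best is not None:
            evidence = "both" if l.gene_id in sim else "synteny"
            calls.append(ConservationCall(l.gene_id, best[2], evidence, -best[0]))
        elif l.gene_id in sim:
            calls.append(ConservationCall(l.gene_id, sim[l.gene_id], "sequence", 0))
        else:
            calls.append(ConservationCall(l.gene_id, None, "none", 0))
    return calls


def conserved_ids(calls: Iterable[ConservationCall]) -> set[str]:
    return {c.lnc_id for c in calls if c.partner is not None}
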