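"""Synthetic two-species genomes and expression panels with planted truth.

Every analysis stage of the pipeline is testable offline against data whose
ground truth is known by construction: gene models for two species with
planted syntenic lncRNAs, a 22-tissue FPKM panel with planted
tissue-specific genes, pre-/mature-adipocyte time courses for two systems
with planted pair-coherence classes, a thermoneutral/cold contrast, and
correlation panels with planted cross-species correlation signs.

Genomes use a cassette layout: each lncRNA sits in its own block with 2-4
protein-coding genes per side, every flanking gene within the synteny
window of its lncRNA, and consecutive blocks separated by more than the
window. A planted perturbation (shuffled or deleted species-B counterpart)
therefore changes exactly one lncRNA's neighbourhood and nothing else. All
genes on a chromosome share its strand.

Randomness comes from one seed; each stage draws from its own
deterministically derived stream, so outputs are bit-identical for an
identical config.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    ExpressionMatrix,
    GeneRecord,
    GenomicInterval,
    OrthologMap,
    TranscriptModel,
)

_STAGES = {
    "assign": 0,
    "coords_a": 1,
    "coords_b": 2,
    "decoys": 3,
    "panel": 4,
    "timecourse": 5,
    "cold": 6,
    "corr": 7,
    "coexpr": 8,
    "fasta": 9,
}

DEPOTS = ("BAT", "oWAT", "sWAT")

FAIL_REASONS = ("coverage", "length", "exons", "coding_potential", "sense_overlap")


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults are the study conditions emulated.

    Counts and thresholds printed by the study (22 tissues, 3 depots,
    +/-500 kb window, 1.5-fold regulation, 0.1/1.0 FPKM detectability,
    pair-class counts 43/22/8/20) are defaults here; distributional
    parameters the study does not state (baseline log2 FPKM, noise SD,
    dominant-tissue share) are package choices documented in the methods
    note.
    """

    seed: int = 1
    n_chroms: int = 4
    chrom_length_bp: int = 40_000_000
    n_coding_genes: int = 760
    n_lncrnas: int = 120
    fraction_tissue_specific: float = 0.5
    n_tissues: int = 22
    n_adipose_depots: int = 3
    fraction_conserved_lnc: float = 0.10
    fraction_desert_lnc: float = 0.15
    window_bp: int = 500_000
    pair_correlation_rho: float = 0.8
    fold_change_magnitude: float = 1.5
    noise_sd_log2: float = 0.4
    specific_share: float = 0.6
    lnc_detect: float = 0.1
    mrna_detect: float = 1.0
    lnc_log2_mean: float = 0.0
    mrna_log2_mean: float = 3.0
    log2_sd: float = 1.5
    fraction_annotated: float = 0.35
    n_decoys_per_type: int = 6
    pair_class_counts: tuple[int, int, int, int] = (43, 22, 8, 20)
    cold_pair_counts: tuple[int, int, int, int] | None = None
    cold_positive_fraction: float = 0.842
    cold_down_bias: float = 0.6
    corr_agree_fraction: float = 0.68
    corr_positive_fraction: float = 0.8
    n_corr_samples: int = 12
    n_coexpr_samples: int = 30
    n_coexpr_partners: int = 15
    n_coexpr_background: int = 150

    def __post_init__(self) -> None:
        if min(self.n_chroms, self.n_coding_genes, self.n_lncrnas,
               self.n_tissues, self.chrom_length_bp) <= 0:
            raise ValueError("all counts must be positive")
        for name in (
            "fraction_tissue_specific", "fraction_conserved_lnc",
            "fraction_desert_lnc", "fraction_annotated", "specific_share",
            "cold_positive_fraction", "corr_agree_fraction",
            "corr_positive_fraction",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (-1 <= self.pair_correlation_rho <= 1):
            raise ValueError("pair_correlation_rho must be in [-1, 1]")
        if self.fold_change_magnitude < 1:
            raise ValueError("fold_change_magnitude must be >= 1")
        if self.noise_sd_log2 < 0 or self.log2_sd < 0:
            raise ValueError("noise/log2 SDs must be >= 0")
        self.pair_class_counts = tuple(self.pair_class_counts)
        if self.cold_pair_counts is not None:
            self.cold_pair_counts = tuple(self.cold_pair_counts)


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(_STAGES[stage],))
    return np.random.default_rng(ss)


@dataclass
class GroundTruth:
    """Planted labels; filled in by the generator stages."""

    catalog_pass: set[str] = field(default_factory=set)
    fail_reason: dict[str, str] = field(default_factory=dict)
    annotated: set[str] = field(default_factory=set)
    conserved: set[str] = field(default_factory=set)
    partner_b: dict[str, str] = field(default_factory=dict)
    desert: set[str] = field(default_factory=set)
    role: dict[str, str] = field(default_factory=dict)
    specific_tissue: dict[str, str | None] = field(default_factory=dict)
    pair_partner: dict[str, str] = field(default_factory=dict)
    pair_class: dict[str, str] = field(default_factory=dict)
    corr_sign: dict[str, tuple[int, int]] = field(default_factory=dict)
    cold_direction: dict[str, tuple[str, str]] = field(default_factory=dict)


@dataclass
class SimulatedGenomes:
    """Gene models for both species plus catalog-stage inputs."""

    config: SimulationConfig
    genes_a: list[GeneRecord]
    lnc_genes_a: list[GeneRecord]
    genes_b: list[GeneRecord]
    lnc_genes_b: list[GeneRecord]
    lnc_transcripts_a: list[TranscriptModel]
    coding_transcripts_a: list[TranscriptModel]
    reference_lnc_a: list[TranscriptModel]
    assemblies: dict[str, list[TranscriptModel]]
    scores: dict[str, float]
    orth: OrthologMap
    truth: GroundTruth

    @property
    def lnc_ids(self) -> list[str]:
        return [g.gene_id for g in self.lnc_genes_a]


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def _make_exons(
    rng: np.random.Generator,
    chrom: str,
    strand: str,
    start: int,
    n_exons: int,
    exon_rng: tuple[int, int],
    intron_rng: tuple[int, int],
) -> tuple[GenomicInterval, ...]:
    exons = []
    cursor = start
    for i in range(n_exons):
        elen = int(rng.integers(exon_rng[0], exon_rng[1] + 1))
        exons.append(GenomicInterval(chrom, cursor, cursor + elen, strand))
        cursor += elen
        if i < n_exons - 1:
            cursor += int(rng.integers(intron_rng[0], intron_rng[1] + 1))
    return tuple(exons)


def _coding_transcripts(
    rng: np.random.Generator, gid: str, chrom: str, strand: str, start: int
) -> list[TranscriptModel]:
    n_exons = int(rng.integers(3, 9))
    exons = _make_exons(rng, chrom, strand, start, n_exons, (100, 300), (200, 2000))
    ts = [TranscriptModel(f"{gid}.t1", gid, exons, biotype="protein_coding")]
    if rng.random() < 0.3 and n_exons >= 4:
        # second isoform skips one internal exon (distinct intron chain)
        skip = int(rng.integers(1, n_exons - 1))
        iso = tuple(e for i, e in enumerate(exons) if i != skip)
        ts.append(TranscriptModel(f"{gid}.t2", gid, iso, biotype="protein_coding"))
    return ts


def _lnc_transcript(
    rng: np.random.Generator, gid: str, chrom: str, strand: str, start: int
) -> TranscriptModel:
    n_exons = int(rng.integers(2, 5))
    exons = _make_exons(rng, chrom, strand, start, n_exons, (120, 400), (100, 1500))
    return TranscriptModel(f"{gid}.t1", gid, exons, biotype="candidate")


def _span_of(transcripts: Sequence[TranscriptModel]) -> GenomicInterval:
    return GenomicInterval(
        transcripts[0].chrom,
        min(t.span.start for t in transcripts),
        max(t.span.end for t in transcripts),
        transcripts[0].strand,
    )


def simulate_gene_models(config: SimulationConfig) -> SimulatedGenomes:
    """Lay out both species' genomes with planted conservation roles.

    Roles per lncRNA: ``conserved`` (species B holds a counterpart with
    identical flanking-gene order through the ortholog map), ``shuffled``
    (counterpart present but the two nearest flanking genes are swapped in
    B, breaking relative order), ``absent`` (no species-B counterpart) or
    ``desert`` (no coding gene within the window; unresolvable by synteny).
    """
    rng = _rng(config, "assign")
    n_lnc = config.n_lncrnas
    n_desert = round(config.fraction_desert_lnc * n_lnc)
    n_conserved = round(config.fraction_conserved_lnc * n_lnc)
    n_nondesert = n_lnc - n_desert
    if n_conserved > n_nondesert:
        raise ValueError(
            "fraction_conserved_lnc + fraction_desert_lnc leave no room: "
            "conserved lncRNAs need flanking genes"
        )
    n_other = n_nondesert - n_conserved
    other_roles = ["absent" if i % 2 == 0 else "shuffled" for i in range(n_other)]
    nondesert_roles = ["conserved"] * n_conserved + other_roles
    rng.shuffle(nondesert_roles)
    roles = nondesert_roles + ["desert"] * n_desert

    # cassette skeletons: gene order only; coordinates drawn per species
    cassettes = []  # (lnc_id | None, role, [left ids], [right ids])
    coding_ids = [f"gA{i:05d}" for i in range(config.n_coding_genes)]
    pool = iter(coding_ids)
    used = 0
    lnc_index = 0
    for role in roles:
        lid = f"lncA{lnc_index:05d}"
        lnc_index += 1
        if role == "desert":
            cassettes.append((lid, role, [], []))
            continue
        n_left = int(rng.integers(2, 5))
        n_right = int(rng.integers(2, 5))
        if used + n_left + n_right > config.n_coding_genes:
            raise ValueError(
                f"n_coding_genes={config.n_coding_genes} too small for "
                f"{n_nondesert} lncRNA cassettes; raise it to at least "
                f"{int(config.n_lncrnas * 8 * 1.1)}"
            )
        left = [next(pool) for _ in range(n_left)]
        right = [next(pool) for _ in range(n_right)]
        used += n_left + n_right
        cassettes.append((lid, role, left, right))
    # leftover coding genes go into coding-only cassettes
    remaining = coding_ids[used:]
    for i in range(0, len(remaining), 6):
        cassettes.append((None, "coding_only", remaining[i : i + 6], []))

    truth = GroundTruth()
    for lid, role, _, _ in cassettes:
        if lid is None:
            continue
        truth.role[lid] = role
        if role == "conserved":
            truth.conserved.add(lid)
            truth.partner_b[lid] = "lncB" + lid[4:]
        elif role == "desert":
            truth.desert.add(lid)

    orth_pairs = [(g, "gB" + g[2:]) for g in coding_ids]
    orth = OrthologMap(orth_pairs)

    def build_species(which: str) -> tuple[
        list[GeneRecord], list[GeneRecord], list[TranscriptModel],
        list[TranscriptModel],
    ]:
        srng = _rng(config, f"coords_{which}")
        spacer = config.window_bp + 120_000
        genes: list[GeneRecord] = []
        lnc_genes: list[GeneRecord] = []
        coding_ts: list[TranscriptModel] = []
        lnc_ts: list[TranscriptModel] = []
        cursors = {f"chr{c + 1}": 60_000 for c in range(config.n_chroms)}
        desert_cursor = 60_000
        strand_of = {
            f"chr{c + 1}": "+" if c % 2 == 0 else "-"
            for c in range(config.n_chroms)
        }
        normal_idx = 0
        for lid, role, left, right in cassettes:
            if role == "desert":
                if which == "b":
                    continue  # deserts only matter for species A calls
                chrom, strand = "chrD", "+"
                t = _lnc_transcript(srng, lid, chrom, strand, desert_cursor)
                desert_cursor = t.span.end + 2 * config.window_bp + 100_000
                lnc_ts.append(t)
                lnc_genes.append(GeneRecord(lid, t.span, "candidate"))
                continue
            chrom = f"chr{normal_idx % config.n_chroms + 1}"
            normal_idx += 1
            strand = strand_of[chrom]
            order: list[str] = list(left) + ([lid] if lid else []) + list(right)
            if which == "b":
                order = [
                    ("lncB" + tok[4:]) if tok.startswith("lncA")
                    else ("gB" + tok[2:])
                    for tok in order
                ]
                if role == "absent" and lid is not None:
                    order = [t for t in order if t.startswith("g")]
                elif role == "shuffled" and lid is not None:
                    # swap the two genes nearest the lncRNA: order breaks
                    i = order.index("lncB" + lid[4:])
                    order[i - 1], order[i + 1] = order[i + 1], order[i - 1]
            cursor = cursors[chrom]
            for tok in order:
                if tok.startswith("lnc"):
                    t = _lnc_transcript(srng, tok, chrom, strand, cursor)
                    lnc_ts.append(t)
                    lnc_genes.append(GeneRecord(tok, t.span, "candidate"))
                    cursor = t.span.end
                else:
                    ts = _coding_transcripts(srng, tok, chrom, strand, cursor)
                    coding_ts.extend(ts)
                    genes.append(GeneRecord(tok, _span_of(ts), "protein_coding"))
                    cursor = max(t.span.end for t in ts)
                cursor += int(srng.integers(20_000, 40_001))
            cursors[chrom] = cursor + spacer
        overflow = max(cursors.values(), default=0)
        if overflow > config.chrom_length_bp:
            raise ValueError(
                f"genes cannot be placed within chrom_length_bp="
                f"{config.chrom_length_bp}; use at least {overflow}"
            )
        return genes, lnc_genes, coding_ts, lnc_ts

    genes_a, lnc_genes_a, coding_ts_a, lnc_ts_a = build_species("a")
    genes_b, lnc_genes_b, _, lnc_ts_b = build_species("b")

    # planted nearest coding partner per non-desert lncRNA (TSS distance)
    coding_by_id = {g.gene_id: g for g in genes_a}
    for lid, role, left, right in cassettes:
        if lid is None or role == "desert":
            continue
        lnc = next(g for g in lnc_genes_a if g.gene_id == lid)
        nearest = min(
            (abs(coding_by_id[g].tss - lnc.tss), g) for g in left + right
        )
        truth.pair_partner[lid] = nearest[1]

    drng = _rng(config, "decoys")
    assemblies, scores, reference, truth = _catalog_inputs(
        config, drng, lnc_ts_a, coding_ts_a, truth
    )
    return SimulatedGenomes(
        config=config,
        genes_a=genes_a,
        lnc_genes_a=lnc_genes_a,
        genes_b=genes_b,
        lnc_genes_b=lnc_genes_b,
        lnc_transcripts_a=lnc_ts_a,
        coding_transcripts_a=coding_ts_a,
        reference_lnc_a=reference,
        assemblies=assemblies,
        scores=scores,
        orth=orth,
        truth=truth,
    )


def _catalog_inputs(
    config: SimulationConfig,
    rng: np.random.Generator,
    lnc_ts: list[TranscriptModel],
    coding_ts: list[TranscriptModel],
    truth: GroundTruth,
):
    """Per-depot assemblies with coverage, decoys failing exactly one
    filter each, coding scores, and the reference lncRNA annotation."""
    scores: dict[str, float] = {}
    depots = DEPOTS[: config.n_adipose_depots]

    candidates: list[TranscriptModel] = []
    for t in lnc_ts:
        cov = {d: float(rng.uniform(0.3, 20.0)) for d in depots}
        cov[depots[int(rng.integers(len(depots)))]] = float(rng.uniform(3.0, 30.0))
        fpkm = {d: float(rng.uniform(0.2, 30.0)) for d in depots}
        candidates.append(
            TranscriptModel(t.transcript_id, t.gene_id, t.exons,
                            biotype="candidate", coverage=cov, fpkm=fpkm)
        )
        scores[t.transcript_id] = float(rng.uniform(-60.0, -2.0))
        truth.catalog_pass.add(t.transcript_id)

    for t in coding_ts:
        cov = {d: float(rng.uniform(3.0, 80.0)) for d in depots}
        fpkm = {d: float(rng.uniform(1.0, 200.0)) for d in depots}
        candidates.append(
            TranscriptModel(t.transcript_id, t.gene_id, t.exons,
                            biotype="candidate", coverage=cov, fpkm=fpkm)
        )
        # genuine mRNAs fail both the coding-potential and sense-overlap
        # filters; attribution to a single filter is not defined for them
        scores[t.transcript_id] = float(rng.uniform(20.0, 800.0))
        truth.fail_reason[t.transcript_id] = "protein_coding"

    # decoys failing exactly one filter each live on their own chromosome,
    # guaranteed free of coding exons and reference lncRNAs
    cursor = 10_000

    def decoy_site() -> int:
        nonlocal cursor
        pos = cursor
        cursor += int(rng.integers(30_000, 60_000))
        return pos

    for i in range(config.n_decoys_per_type):
        # (1) fails coverage only
        t = _lnc_transcript(rng, f"decoyCov{i:03d}", "chrU", "+", decoy_site())
        cov = {d: float(rng.uniform(0.05, 2.9)) for d in depots}
        candidates.append(TranscriptModel(t.transcript_id, t.gene_id, t.exons,
                                          coverage=cov))
        scores[t.transcript_id] = float(rng.uniform(-60.0, -2.0))
        truth.fail_reason[t.transcript_id] = "coverage"
        # (2) fails length only: two exons totalling <200 bp even after the
        # per-tissue 3'-end jitter (up to +50 bp) applied in the assemblies
        exons = _make_exons(rng, "chrU", "+", decoy_site(), 2, (40, 70), (200, 800))
        cov = {d: float(rng.uniform(3.0, 20.0)) for d in depots}
        tid = f"decoyLen{i:03d}"
        candidates.append(TranscriptModel(tid, tid, exons, coverage=cov))
        scores[tid] = float(rng.uniform(-60.0, -2.0))
        truth.fail_reason[tid] = "length"
        # (3) fails exon count only (one long exon)
        exons = _make_exons(rng, "chrU", "+", decoy_site(), 1, (500, 2000), (0, 0))
        cov = {d: float(rng.uniform(3.0, 20.0)) for d in depots}
        tid = f"decoyMono{i:03d}"
        candidates.append(TranscriptModel(tid, tid, exons, coverage=cov))
        scores[tid] = float(rng.uniform(-60.0, -2.0))
        truth.fail_reason[tid] = "exons"
        # (4) fails coding potential only
        t = _lnc_transcript(rng, f"decoyCds{i:03d}", "chrU", "+", decoy_site())
        cov = {d: float(rng.uniform(3.0, 20.0)) for d in depots}
        candidates.append(TranscriptModel(t.transcript_id, t.gene_id, t.exons,
                                          coverage=cov))
        scores[t.transcript_id] = float(rng.uniform(5.0, 80.0))
        truth.fail_reason[t.transcript_id] = "coding_potential"

    # (5) fails sense overlap only: first two exons borrowed from coding genes
    overlap_hosts = rng.choice(len(coding_ts), size=config.n_decoys_per_type,
                               replace=False)
    for i, hi in enumerate(overlap_hosts):
        host = coding_ts[int(hi)]
        e0, e1 = host.exons[0], host.exons[1]
        exons = (
            GenomicInterval(e0.chrom, e0.start + 5, e0.end + 15, e0.strand),
            GenomicInterval(e1.chrom, e1.start + 5, e1.end + 15, e1.strand),
        )
        cov = {d: float(rng.uniform(3.0, 20.0)) for d in depots}
        tid = f"decoyOvl{i:03d}"
        candidates.append(TranscriptModel(tid, tid, exons, coverage=cov))
        scores[tid] = float(rng.uniform(-60.0, -2.0))
        truth.fail_reason[tid] = "sense_overlap"

    # per-depot assemblies: same molecules with jittered 3'-terminal ends
    assemblies: dict[str, list[TranscriptModel]] = {d: [] for d in depots}
    for t in candidates:
        for d in depots:
            if t.n_exons >= 2:
                last = t.exons[-1]
                ext = int(rng.integers(0, 51))
                exons = t.exons[:-1] + (
                    GenomicInterval(last.chrom, last.start, last.end + ext,
                                    last.strand),
                )
            else:
                exons = t.exons  # single-exon models match on exact span
            assemblies[d].append(
                TranscriptModel(
                    t.transcript_id, t.gene_id, exons, biotype=t.biotype,
                    coverage={d: t.coverage[d]} if d in t.coverage else {},
                    fpkm={d: t.fpkm[d]} if d in t.fpkm else {},
                )
            )

    # reference lncRNA annotation: a fraction of the true lncRNAs are known
    n_known = round(config.fraction_annotated * len(lnc_ts))
    known_idx = set(map(int, rng.choice(len(lnc_ts), size=n_known, replace=False)))
    reference = []
    for i in sorted(known_idx):
        t = lnc_ts[i]
        reference.append(
            TranscriptModel("REF_" + t.transcript_id, "REF_" + t.gene_id,
                            t.exons, biotype="reference_lncRNA")
        )
        truth.annotated.add(t.gene_id)
    return assemblies, scores, reference, truth


# ---------------------------------------------------------------------------
# expression panel
# ---------------------------------------------------------------------------

def tissue_names(n_tissues: int) -> list[str]:
    extra = [f"tissue{i:02d}" for i in range(4, n_tissues + 1)]
    return list(DEPOTS) + extra


def simulate_expression_panel(
    config: SimulationConfig, sim: SimulatedGenomes
) -> ExpressionMatrix:
    """22-tissue FPKM panel with planted tissue-specific genes.

    Planted specific genes put ``specific_share`` of their expression into
    one tissue; broad genes draw a near-uniform Dirichlet allocation capped
    below the 0.1 specificity threshold so zero-noise classification is
    exact. Conserved lncRNAs are always broad (they are the ubiquitously
    expressed class); the planted specific fraction applies to the
    remaining lncRNAs, and to mRNAs at 0.4x that rate.
    """
    rng = _rng(config, "panel")
    tissues = tissue_names(config.n_tissues)
    lnc_ids = sim.lnc_ids
    coding_ids = [g.gene_id for g in sim.genes_a]

    nonconserved = [g for g in lnc_ids if g not in sim.truth.conserved]
    n_spec_lnc = min(
        round(config.fraction_tissue_specific * len(lnc_ids)), len(nonconserved)
    )
    spec_lnc = {
        str(g)
        for g in np.array(nonconserved)[
            rng.choice(len(nonconserved), size=n_spec_lnc, replace=False)
        ]
    }
    n_spec_m = round(0.4 * config.fraction_tissue_specific * len(coding_ids))
    spec_m = {
        str(g)
        for g in np.array(coding_ids)[
            rng.choice(len(coding_ids), size=n_spec_m, replace=False)
        ]
    }

    # broad genes stay strictly below the 0.1 call threshold so zero-noise
    # classification is exact; only achievable on panels wide enough for a
    # near-uniform allocation to sit under 0.1
    cap = 0.095 if config.n_tissues >= 12 else 1.0

    def broad_alloc() -> np.ndarray:
        while True:
            f = rng.dirichlet([30.0] * config.n_tissues)
            if f.max() < cap:
                return f

    rows = []
    classes = {}
    for gid in lnc_ids + coding_ids:
        is_lnc = gid in set(lnc_ids)
        classes[gid] = "lncRNA" if is_lnc else "mRNA"
        mean = config.lnc_log2_mean if is_lnc else config.mrna_log2_mean
        base = 2.0 ** rng.normal(mean, config.log2_sd)
        if gid in spec_lnc or gid in spec_m:
            t_idx = int(rng.integers(config.n_tissues))
            alloc = np.full(
                config.n_tissues,
                (1 - config.specific_share) / (config.n_tissues - 1),
            )
            alloc[t_idx] = config.specific_share
            sim.truth.specific_tissue[gid] = tissues[t_idx]
        else:
            alloc = broad_alloc()
            sim.truth.specific_tissue[gid] = None
        noise = 2.0 ** rng.normal(0.0, config.noise_sd_log2, config.n_tissues)
        rows.append(base * config.n_tissues * alloc * noise)
    values = pd.DataFrame(rows, index=lnc_ids + coding_ids, columns=tissues)
    return ExpressionMatrix(values, pd.Series(classes))


# ---------------------------------------------------------------------------
# time courses, cold contrast, correlation panels
# ---------------------------------------------------------------------------

_CLASS_DIRS = {
    # per class: ((lnc ds1, lnc ds2), (mrna ds1, mrna ds2)) sign templates
    "coherent_up": ((1, 1), (1, 1)),
    "coherent_down": ((-1, -1), (-1, -1)),
    "anti": ((1, 1), (-1, -1)),
    "incoherent": ((1, 1), (1, -1)),
}


def _mag(rng: np.random.Generator, config: SimulationConfig) -> float:
    lo = math.log2(config.fold_change_magnitude) + 0.915
    return float(rng.uniform(lo, lo + 1.5))


def simulate_timecourse(
    config: SimulationConfig, sim: SimulatedGenomes
) -> dict[str, tuple[ExpressionMatrix, ExpressionMatrix]]:
    """Pre-/mature-adipocyte contrasts for two systems (primary cells and
    clonal cell lines) with planted pair-coherence classes.

    The first ``sum(pair_class_counts)`` lncRNA-mRNA pairs (order
    randomised per seed) are regulated with class-determined direction
    signs; magnitudes are drawn well above the 1.5-fold call threshold.
    Remaining genes drift near fold change 1.
    """
    rng = _rng(config, "timecourse")
    pairs = sorted(sim.truth.pair_partner.items())
    n_planted = sum(config.pair_class_counts)
    if n_planted > len(pairs):
        raise ValueError(
            f"pair_class_counts needs {n_planted} pairs but only "
            f"{len(pairs)} lncRNAs have coding partners"
        )
    labels = [
        cls
        for cls, n in zip(_CLASS_DIRS, config.pair_class_counts)
        for _ in range(n)
    ]
    order = rng.permutation(len(pairs))
    planted = [pairs[i] for i in order[:n_planted]]
    for (lnc, _), cls in zip(planted, labels):
        sim.truth.pair_class[lnc] = cls

    lnc_ids = sim.lnc_ids
    coding_ids = [g.gene_id for g in sim.genes_a]
    genes = lnc_ids + coding_ids
    classes = pd.Series(
        ["lncRNA"] * len(lnc_ids) + ["mRNA"] * len(coding_ids), index=genes
    )

    # planted log2 fold change per gene per dataset (0 = unregulated drift)
    fc = {ds: dict.fromkeys(genes, None) for ds in ("primary", "cellline")}
    for (lnc, mrna), cls in zip(planted, labels):
        lnc_t, mrna_t = _CLASS_DIRS[cls]
        if cls == "anti":
            s = int(rng.choice([-1, 1]))
            lnc_t = (s, s)
            mrna_t = (-s, -s)
        for di, ds in enumerate(("primary", "cellline")):
            fc[ds][lnc] = lnc_t[di] * _mag(rng, config)
            fc[ds][mrna] = mrna_t[di] * _mag(rng, config)

    out = {}
    for ds in ("primary", "cellline"):
        pre_vals, post_vals = [], []
        for g in genes:
            floor = 0.4 if classes[g] == "lncRNA" else 2.0
            mean = 2.0 if classes[g] == "lncRNA" else 4.0
            pre = max(floor, 2.0 ** rng.normal(mean, 1.0))
            delta = fc[ds][g]
            if delta is None:
                delta = rng.normal(0.0, 0.15)
            post = pre * 2.0 ** delta
            pre *= 2.0 ** rng.normal(0.0, config.noise_sd_log2)
            post *= 2.0 ** rng.normal(0.0, config.noise_sd_log2)
            pre_vals.append(pre)
            post_vals.append(post)
        pre_m = ExpressionMatrix(
            pd.DataFrame({"pre": pre_vals}, index=genes), classes
        )
        post_m = ExpressionMatrix(
            pd.DataFrame({"mature": post_vals}, index=genes), classes
        )
        out[ds] = (pre_m, post_m)
    return out


def simulate_cold_contrast(
    config: SimulationConfig, sim: SimulatedGenomes
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Thermoneutral vs cold-exposure contrast with planted pair directions.

    Cell counts (lnc-up/mrna-up, up/down, down/up, down/down) come from
    ``cold_pair_counts`` when set; otherwise they are derived from the
    positive fraction and the downregulation bias over all available pairs.
    """
    rng = _rng(config, "cold")
    pairs = sorted(sim.truth.pair_partner.items())
    n = len(pairs)
    if config.cold_pair_counts is not None:
        counts = config.cold_pair_counts
        if sum(counts) > n:
            raise ValueError(
                f"cold_pair_counts needs {sum(counts)} pairs, have {n}"
            )
    else:
        same = round(config.cold_positive_fraction * n)
        dd = round(config.cold_down_bias * same)
        uu = same - dd
        du = (n - same) // 2
        ud = n - same - du
        counts = (uu, ud, du, dd)
    templates = [("up", "up"), ("up", "down"), ("down", "up"), ("down", "down")]
    labels = [t for t, c in zip(templates, counts) for _ in range(c)]
    order = rng.permutation(n)
    for i, lab in zip(order, labels):
        sim.truth.cold_direction[pairs[i][0]] = lab

    lnc_ids = sim.lnc_ids
    coding_ids = [g.gene_id for g in sim.genes_a]
    genes = lnc_ids + coding_ids
    classes = pd.Series(
        ["lncRNA"] * len(lnc_ids) + ["mRNA"] * len(coding_ids), index=genes
    )
    sign = {"up": 1, "down": -1}
    fc = dict.fromkeys(genes, None)
    for i, lab in zip(order, labels):
        lnc, mrna = pairs[i]
        fc[lnc] = sign[lab[0]] * _mag(rng, config)
        fc[mrna] = sign[lab[1]] * _mag(rng, config)

    tn_vals, cold_vals = [], []
    for g in genes:
        floor = 0.4 if classes[g] == "lncRNA" else 2.0
        mean = 2.0 if classes[g] == "lncRNA" else 4.0
        tn = max(floor, 2.0 ** rng.normal(mean, 1.0))
        delta = fc[g] if fc[g] is not None else rng.normal(0.0, 0.15)
        cold = tn * 2.0 ** delta
        tn *= 2.0 ** rng.normal(0.0, config.noise_sd_log2)
        cold *= 2.0 ** rng.normal(0.0, config.noise_sd_log2)
        tn_vals.append(tn)
        cold_vals.append(cold)
    tn_m = ExpressionMatrix(pd.DataFrame({"TN": tn_vals}, index=genes), classes)
    cold_m = ExpressionMatrix(pd.DataFrame({"CE": cold_vals}, index=genes), classes)
    return tn_m, cold_m


def simulate_correlation_panels(
    config: SimulationConfig, sim: SimulatedGenomes
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Per-species sample panels with planted lncRNA-mRNA correlation signs
    for every conserved pair.

    Pair members share a latent sample effect: member = sign * (rho * z +
    noise_sd * eps) on the log2 scale, so with the noise off the pair
    correlation is exactly +/-1 and the planted sign is recovered exactly.
    ``corr_agree_fraction`` of conserved pairs keep their sign across
    species.
    """
    rng = _rng(config, "corr")
    n_s = config.n_corr_samples
    samples = [f"s{i:02d}" for i in range(n_s)]
    conserved = sorted(sim.truth.conserved - sim.truth.desert)

    lnc_a = sim.lnc_ids
    coding_a = [g.gene_id for g in sim.genes_a]
    lnc_b = [g.gene_id for g in sim.lnc_genes_b]
    coding_b = [g.gene_id for g in sim.genes_b]
    genes = {"a": lnc_a + coding_a, "b": lnc_b + coding_b}
    classes = {
        "a": pd.Series(["lncRNA"] * len(lnc_a) + ["mRNA"] * len(coding_a),
                       index=genes["a"]),
        "b": pd.Series(["lncRNA"] * len(lnc_b) + ["mRNA"] * len(coding_b),
                       index=genes["b"]),
    }

    log2 = {sp: {g: rng.normal(0.0, 1.0, n_s) for g in genes[sp]}
            for sp in ("a", "b")}
    rho = abs(config.pair_correlation_rho)
    for lnc in conserved:
        mrna = sim.truth.pair_partner[lnc]
        lnc_b_id = sim.truth.partner_b[lnc]
        mrna_b_id = sim.orth.to_b(mrna)
        sign_a = 1 if rng.random() < config.corr_positive_fraction else -1
        sign_b = sign_a if rng.random() < config.corr_agree_fraction else -sign_a
        sim.truth.corr_sign[lnc] = (sign_a, sign_b)
        for sp, s, l_id, m_id in (
            ("a", sign_a, lnc, mrna),
            ("b", sign_b, lnc_b_id, mrna_b_id),
        ):
            z = rng.normal(0.0, 1.0, n_s)
            eps = rng.normal(0.0, 1.0, n_s)
            log2[sp][l_id] = z
            log2[sp][m_id] = s * (rho * z + config.noise_sd_log2 * eps)

    mats = []
    for sp in ("a", "b"):
        vals = pd.DataFrame(
            {g: 2.0 ** (3.0 + log2[sp][g]) for g in genes[sp]}, index=samples
        ).T
        mats.append(ExpressionMatrix(vals, classes[sp]))
    return mats[0], mats[1]


def simulate_coexpression_panel(
    config: SimulationConfig, sim: SimulatedGenomes
) -> tuple[ExpressionMatrix, str, set[str], "GeneSetCollection"]:
    """Sample panel for guilt-by-association with a planted partner module.

    The query lncRNA and its planted partners share a latent sample effect
    (affine at zero noise, so the R >= 0.7 selection recovers the module
    exactly); background coding genes are independent. Returns the panel,
    the query id, the planted partner set, and a GMT-style collection whose
    first set is loaded with partners.
    """
    from .model import GeneSetCollection

    rng = _rng(config, "coexpr")
    n_s = config.n_coexpr_samples
    samples = [f"c{i:02d}" for i in range(n_s)]
    query = sorted(sim.truth.conserved - sim.truth.desert)[0] if sim.truth.conserved \
        else sim.lnc_ids[0]
    coding_ids = [g.gene_id for g in sim.genes_a]
    background = coding_ids[: config.n_coexpr_background]
    partners = {
        str(g)
        for g in np.array(background)[
            rng.choice(len(background), size=config.n_coexpr_partners, replace=False)
        ]
    }
    z = rng.normal(0.0, 1.0, n_s)
    rho = abs(config.pair_correlation_rho)
    rows = {query: z}
    for g in background:
        if g in partners:
            rows[g] = rho * z + config.noise_sd_log2 * rng.normal(0.0, 1.0, n_s)
        else:
            rows[g] = rng.normal(0.0, 1.0, n_s)
    vals = pd.DataFrame(
        {g: 2.0 ** (3.0 + rows[g]) for g in rows}, index=samples
    ).T
    classes = pd.Series(
        {g: ("lncRNA" if g == query else "mRNA") for g in rows}
    )

    # gene sets: one loaded with the partner module, the rest random
    sets = {}
    loaded = {str(g) for g in rng.choice(sorted(partners),
                                         size=min(10, len(partners)),
                                         replace=False)}
    filler = [g for g in background if g not in loaded]
    sets["PLANTED_MODULE"] = frozenset(
        loaded | {str(g) for g in rng.choice(filler, size=8, replace=False)}
    )
    for i in range(9):
        sets[f"RANDOM_SET_{i:02d}"] = frozenset(
            str(g) for g in rng.choice(background, size=18, replace=False)
        )
    return (
        ExpressionMatrix(vals, classes),
        query,
        partners,
        GeneSetCollection(sets, universe=frozenset(background)),
    )


def simulate_sequences(
    config: SimulationConfig, transcripts: Sequence[TranscriptModel]
) -> dict[str, str]:
    """Random-base transcript sequences (no sequence realism; ORF-scan fodder)."""
    rng = _rng(config, "fasta")
    bases = np.array(list("ACGT"))
    return {
        t.transcript_id: "".join(
            bases[rng.integers(0, 4, size=sum(e.length for e in t.exons))]
        )
        for t in transcripts
    }


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["pair_class_counts"] = list(config.pair_class_counts)
    if config.cold_pair_counts is not None:
        d["cold_pair_counts"] = list(config.cold_pair_counts)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
    return SimulationConfig(**d)
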