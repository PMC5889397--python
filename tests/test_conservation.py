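"""Synteny contexts, order matching, and planted conservation recovery."""
import numpy as np
import pytest

from adipolnc.conservation import (
    build_context,
    conserved_catalog,
    conserved_ids,
    synteny_match,
)
from adipolnc.model import GeneRecord, GenomicInterval, OrthologMap
from adipolnc.synthetic import SimulationConfig, simulate_gene_models

W = 500_000


def gene(gid, chrom, start, end, strand="+", biotype="protein_coding"):
    return GeneRecord(gid, GenomicInterval(chrom, start, end, strand), biotype)


def lnc(gid, chrom, start, end, strand="+"):
    return GeneRecord(gid, GenomicInterval(chrom, start, end, strand), "candidate")


def layout(*specs, chrom="chr1", strand="+"):
    """specs: (id, start, end, kind) with kind 'c' coding / 'l' lncRNA."""
    genes, lncs = [], []
    for gid, s, e, kind in specs:
        if kind == "c":
            genes.append(gene(gid, chrom, s, e, strand))
        else:
            lncs.append(lnc(gid, chrom, s, e, strand))
    return genes, lncs


def test_window_boundary_inclusive():
    l = lnc("L", "chr1", 1_000_000, 1_002_000)
    at_boundary = gene("g1", "chr1", 499_000, 500_000)  # gap exactly W
    beyond = gene("g2", "chr1", 498_999, 499_999)  # gap W + 1
    ctx = build_context(l, [at_boundary, beyond], W)
    assert ctx.gene_ids == ("g1",)


def test_opposite_strand_and_non_coding_excluded():
    l = lnc("L", "chr1", 1_000_000, 1_002_000, strand="+")
    minus = gene("g1", "chr1", 900_000, 910_000, strand="-")
    not_coding = gene("g2", "chr1", 950_000, 960_000, biotype="candidate")
    ok = gene("g3", "chr1", 970_000, 980_000)
    ctx = build_context(l, [minus, not_coding, ok], W)
    assert ctx.gene_ids == ("g3",)


def _identity_setup():
    genes_a, lncs_a = layout(
        ("a1", 100_000, 110_000, "c"), ("a2", 200_000, 210_000, "c"),
        ("LA", 300_000, 302_000, "l"), ("a3", 400_000, 410_000, "c"),
    )
    genes_b, lncs_b = layout(
        ("b1", 500_000, 505_000, "c"), ("b2", 600_000, 606_000, "c"),
        ("LB", 700_000, 702_000, "l"), ("b3", 800_000, 808_000, "c"),
        chrom="chr9",
    )
    orth = OrthologMap([("a1", "b1"), ("a2", "b2"), ("a3", "b3")])
    return genes_a, lncs_a[0], genes_b, lncs_b[0], orth


def test_synteny_identity_order_matches():
    genes_a, la, genes_b, lb, orth = _identity_setup()
    ctx_a = build_context(la, genes_a, W)
    ctx_b = build_context(lb, genes_b, W)
    ok, shared = synteny_match(ctx_a, ctx_b, orth)
    assert ok and shared == 3


def test_synteny_broken_order_fails():
    genes_a, la, genes_b, lb, orth = _identity_setup()
    # swap b1 and b2 genomically: relative order breaks
    genes_b[0].span = GenomicInterval("chr9", 600_000, 606_000, "+")
    genes_b[1].span = GenomicInterval("chr9", 500_000, 505_000, "+")
    ok, _ = synteny_match(
        build_context(la, genes_a, W), build_context(lb, genes_b, W), orth
    )
    assert not ok


def test_sidedness_must_be_preserved():
    genes_a, la, genes_b, lb, orth = _identity_setup()
    # move b3 upstream of the lncRNA: order a1,a2,LNC,a3 vs b3,b1,b2,LNC
    genes_b[2].span = GenomicInterval("chr9", 400_000, 408_000, "+")
    ok, _ = synteny_match(
        build_context(la, genes_a, W), build_context(lb, genes_b, W), orth
    )
    assert not ok


def test_strand_inversion_allows_reversed_context():
    genes_a, la, genes_b, lb, orth = _identity_setup()
    # species-B block on the minus strand with mirrored gene order
    genes_b_inv, lncs_b_inv = layout(
        ("b3", 500_000, 505_000, "c"), ("LB", 600_000, 602_000, "l"),
        ("b2", 700_000, 706_000, "c"), ("b1", 800_000, 808_000, "c"),
        chrom="chr9", strand="-",
    )
    ok, shared = synteny_match(
        build_context(la, genes_a, W),
        build_context(lncs_b_inv[0], genes_b_inv, W),
        orth,
    )
    assert ok and shared == 3
    ok_no_inv, _ = synteny_match(
        build_context(la, genes_a, W),
        build_context(lncs_b_inv[0], genes_b_inv, W),
        orth,
        allow_inversion=False,
    )
    assert not ok_no_inv


def test_min_shared_requires_two_genes():
    genes_a, lncs_a = layout(("a1", 100_000, 110_000, "c"),
                             ("LA", 300_000, 302_000, "l"))
    genes_b, lncs_b = layout(("b1", 100_000, 110_000, "c"),
                             ("LB", 300_000, 302_000, "l"), chrom="chr2")
    orth = OrthologMap([("a1", "b1")])
    ok, shared = synteny_match(
        build_context(lncs_a[0], genes_a, W),
        build_context(lncs_b[0], genes_b, W),
        orth,
    )
    assert not ok and shared == 1


def test_gene_desert_is_unresolvable():
    la = lnc("L", "chr1", 5_000_000, 5_002_000)
    ctx = build_context(la, [], W)
    assert ctx.is_desert
    genes_b, lncs_b = layout(
        ("b1", 100_000, 110_000, "c"), ("b2", 200_000, 206_000, "c"),
        ("LB", 300_000, 302_000, "l"),
    )
    ok, shared = synteny_match(
        ctx, build_context(lncs_b[0], genes_b, W), OrthologMap([])
    )
    assert not ok and shared == 0


def test_empty_catalog_b_and_empty_orthologs_yield_zero_calls():
    genes_a, lncs_a = layout(
        ("a1", 100_000, 110_000, "c"), ("a2", 200_000, 210_000, "c"),
        ("LA", 300_000, 302_000, "l"),
    )
    calls = conserved_catalog(lncs_a, [], genes_a, [], OrthologMap([]))
    assert conserved_ids(calls) == set()


def test_similarity_only_pair_gets_sequence_evidence():
    genes_a, la, genes_b, lb, orth = _identity_setup()
    # break synteny, keep the sequence hit
    genes_b[0].span = GenomicInterval("chr9", 600_000, 606_000, "+")
    genes_b[1].span = GenomicInterval("chr9", 500_000, 505_000, "+")
    calls = conserved_catalog(
        [la], [lb], genes_a, genes_b, orth, similarity_hits=[("LA", "LB")]
    )
    (call,) = calls
    assert call.partner == "LB" and call.evidence == "sequence"
    # unknown ids in the similarity table are skipped, not fatal
    calls2 = conserved_catalog(
        [la], [lb], genes_a, genes_b, orth, similarity_hits=[("nope", "LB")]
    )
    assert calls2[0].partner is None


def test_planted_conservation_recovered_exactly(small_sim):
    calls = conserved_catalog(
        small_sim.lnc_genes_a, small_sim.lnc_genes_b,
        small_sim.genes_a, small_sim.genes_b, small_sim.orth,
    )
    assert conserved_ids(calls) == small_sim.truth.conserved
    by_id = {c.lnc_id: c for c in calls}
    for lnc_id in small_sim.truth.conserved:
        assert by_id[lnc_id].partner == small_sim.truth.partner_b[lnc_id]
        assert by_id[lnc_id].evidence == "synteny"
    for lnc_id in small_sim.truth.desert:
        assert by_id[lnc_id].partner is None


def test_all_or_none_conserved_fractions():
    base = dict(seed=3, n_chroms=2, chrom_length_bp=20_000_000,
                n_coding_genes=130, n_lncrnas=12, fraction_desert_lnc=0.0,
                pair_class_counts=(2, 1, 1, 1), n_decoys_per_type=2)
    all_cons = simulate_gene_models(
        SimulationConfig(fraction_conserved_lnc=1.0, **base)
    )
    calls = conserved_catalog(all_cons.lnc_genes_a, all_cons.lnc_genes_b,
                              all_cons.genes_a, all_cons.genes_b, all_cons.orth)
    assert conserved_ids(calls) == {g.gene_id for g in all_cons.lnc_genes_a}
    none_cons = simulate_gene_models(
        SimulationConfig(fraction_conserved_lnc=0.0, **base)
    )
    calls0 = conserved_catalog(none_cons.lnc_genes_a, none_cons.lnc_genes_b,
                               none_cons.genes_a, none_cons.genes_b,
                               none_cons.orth)
    assert conserved_ids(calls0) == set()


def test_symmetry_of_matched_pairs(small_sim):
    forward = conserved_catalog(
        small_sim.lnc_genes_a, small_sim.lnc_genes_b,
        small_sim.genes_a, small_sim.genes_b, small_sim.orth,
    )
    reversed_orth = OrthologMap(
        [(b, a) for a, b in small_sim.orth.a2b.items()]
    )
    backward = conserved_catalog(
        small_sim.lnc_genes_b, small_sim.lnc_genes_a,
        small_sim.genes_b, small_sim.genes_a, reversed_orth,
    )
    fwd = {(c.lnc_id, c.partner) for c in forward if c.partner}
    bwd = {(c.partner, c.lnc_id) for c in backward if c.partner}
    assert fwd == bwd


def test_window_monotonicity_on_synthetic_ensemble(small_sim):
    calls_small = conserved_catalog(
        small_sim.lnc_genes_a, small_sim.lnc_genes_b,
        small_sim.genes_a, small_sim.genes_b, small_sim.orth,
        window_bp=300_000,
    )
    calls_big = conserved_catalog(
        small_sim.lnc_genes_a, small_sim.lnc_genes_b,
        small_sim.genes_a, small_sim.genes_b, small_sim.orth,
        window_bp=500_000,
    )
    assert conserved_ids(calls_small) <= conserved_ids(calls_big)
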