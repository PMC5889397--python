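"""Filter cascade, ORF scan, intron-chain matching and novelty labelling."""
import itertools

import numpy as np
import pytest

from adipolnc.catalog import (
    FILTER_NAMES,
    ExonOverlapIndex,
    FilterConfig,
    build_catalog,
    longest_orf,
    match_by_intron_chain,
    sense_overlaps_coding,
    transcript_length,
)
from adipolnc.model import GenomicInterval

from conftest import make_transcript


# --- transcript length ------------------------------------------------------

def test_transcript_length_examples():
    assert transcript_length(make_transcript("t", "c", "+", [(0, 100), (200, 350)])) == 250
    # 200 bp passes the >=200 criterion exactly at the boundary
    assert transcript_length(make_transcript("t", "c", "+", [(5, 205)])) == 200


def test_transcript_length_random_against_resummation():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(1, 8))
        cursor, coords = 0, []
        for _ in range(n):
            cursor += int(rng.integers(1, 500))
            end = cursor + int(rng.integers(1, 400))
            coords.append((cursor, end))
            cursor = end
        t = make_transcript("t", "c", "+", coords)
        assert transcript_length(t) == sum(e - s for s, e in coords)


# --- ORF scan ---------------------------------------------------------------

def _brute_orf(seq):
    stops = {"TAA", "TAG", "TGA"}
    best = 0
    for i in range(len(seq)):
        if seq[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, len(seq) - 2, 3):
            if seq[j : j + 3] in stops:
                best = max(best, j + 3 - i)
                break
    return best


def test_longest_orf_examples():
    assert longest_orf("ATGAAATGA") == 9
    assert longest_orf("CCCCCC") == 0
    with pytest.raises(ValueError, match="non-IUPAC"):
        longest_orf("ATGXXX")


def test_longest_orf_against_exhaustive_scan():
    rng = np.random.default_rng(1)
    bases = np.array(list("ACGT"))
    for _ in range(40):
        seq = "".join(bases[rng.integers(0, 4, size=300)])
        assert longest_orf(seq) == _brute_orf(seq)


# --- sense overlap ----------------------------------------------------------

def test_sense_overlap_strand_and_intron_contract():
    coding_plus = make_transcript("c", "chr1", "+", [(150, 250)])
    coding_minus = make_transcript("c", "chr1", "-", [(150, 250)])
    idx_plus = ExonOverlapIndex([coding_plus])
    idx_minus = ExonOverlapIndex([coding_minus])
    t = make_transcript("t", "chr1", "+", [(100, 200)])
    assert sense_overlaps_coding(t, idx_plus) is True
    assert sense_overlaps_coding(t, idx_minus) is False
    # coding exon entirely inside the intron does not count
    spliced = make_transcript("s", "chr1", "+", [(100, 200), (400, 500)])
    idx_intronic = ExonOverlapIndex([make_transcript("c", "chr1", "+", [(250, 350)])])
    assert sense_overlaps_coding(spliced, idx_intronic) is False


# --- intron-chain matching --------------------------------------------------

def test_intron_chain_unifies_on_chain_not_terminal_ends():
    a = make_transcript("a", "chr1", "+", [(100, 200), (300, 400)],
                        coverage={"BAT": 5.0})
    b = make_transcript("b", "chr1", "+", [(90, 200), (300, 450)],
                        coverage={"sWAT": 2.0})
    unified = match_by_intron_chain({"BAT": [a], "sWAT": [b]})
    assert len(unified) == 1
    assert unified[0].coverage == {"BAT": 5.0, "sWAT": 2.0}


def test_intron_chain_respects_strand():
    a = make_transcript("a", "chr1", "+", [(100, 200), (300, 400)])
    b = make_transcript("b", "chr1", "-", [(100, 200), (300, 400)])
    assert len(match_by_intron_chain({"x": [a], "y": [b]})) == 2


def test_intron_chain_enumeration_over_three_assemblies():
    # chains: A shared by all 3; B in two; C single-exon shared on exact
    # span; D single-exon differing span -> 4 unified transcripts
    chain_a = [(0, 100), (200, 300)]
    chain_b = [(1000, 1100), (1300, 1400), (1500, 1600)]
    mk = make_transcript
    assemblies = {
        "t1": [mk("a1", "c", "+", chain_a), mk("b1", "c", "+", chain_b),
               mk("c1", "c", "+", [(5000, 5500)])],
        "t2": [mk("a2", "c", "+", [(10, 100), (200, 280)]),
               mk("b2", "c", "+", chain_b)],
        "t3": [mk("a3", "c", "+", chain_a), mk("c3", "c", "+", [(5000, 5500)]),
               mk("d3", "c", "+", [(5000, 5600)])],
    }
    assert len(match_by_intron_chain(assemblies)) == 4


# --- build_catalog ----------------------------------------------------------

@pytest.fixture()
def toy_filter_set():
    """Six transcripts failing exactly one criterion each plus one passing."""
    mk = make_transcript
    cov = {"BAT": 5.0}
    coding = mk("coding", "chr1", "+", [(50_000, 50_400), (51_000, 51_400)])
    candidates = [
        mk("pass", "chr1", "+", [(100, 300), (500, 800)], coverage=cov),
        mk("failCov", "chr1", "+", [(2000, 2300), (2500, 2900)],
           coverage={"BAT": 2.9, "oWAT": 0.0}),
        mk("failLen", "chr1", "+", [(4000, 4090), (4200, 4299)], coverage=cov),
        mk("failExons", "chr1", "+", [(6000, 6900)], coverage=cov),
        mk("failCoding", "chr1", "+", [(8000, 8300), (8500, 8900)], coverage=cov),
        mk("failOverlap", "chr1", "+", [(50_100, 50_300), (52_000, 52_400)],
           coverage=cov),
    ]
    scores = {t.transcript_id: -10.0 for t in candidates}
    scores["failCoding"] = 12.0
    return candidates, scores, [coding]


def test_build_catalog_attributes_one_removal_per_filter(toy_filter_set):
    candidates, scores, coding = toy_filter_set
    catalog, report = build_catalog(candidates, FilterConfig(), scores, coding)
    assert [t.transcript_id for t in catalog] == ["pass"]
    assert report.fates == {
        "failCov": "coverage",
        "failLen": "length",
        "failExons": "exons",
        "failCoding": "coding_potential",
        "failOverlap": "sense_overlap",
    }
    assert report.n_input == report.n_final + sum(report.removals.values())
    # telescoping: each stage's output is the next stage's input
    for (_, _, n_out), (_, n_in, _) in zip(report.stages, report.stages[1:]):
        assert n_out == n_in


def test_filter_order_invariance(toy_filter_set):
    candidates, scores, coding = toy_filter_set
    reference = None
    for perm in itertools.permutations(FILTER_NAMES):
        catalog, _ = build_catalog(
            candidates, FilterConfig(), scores, coding, filter_order=perm
        )
        ids = sorted(t.transcript_id for t in catalog)
        if reference is None:
            reference = ids
        assert ids == reference


def test_coverage_boundary_inclusive():
    t = make_transcript("t", "chr1", "+", [(0, 300), (500, 900)],
                        coverage={"BAT": 3.0, "oWAT": 0.0})
    catalog, _ = build_catalog([t], FilterConfig(), {"t": -5.0}, [])
    assert len(catalog) == 1


def test_novelty_partition_and_coextensive_annotated():
    t = make_transcript("t", "chr1", "+", [(100, 300), (500, 800)],
                        coverage={"BAT": 4.0})
    ref = make_transcript("ref", "chr1", "+", [(100, 300), (500, 800)],
                          biotype="reference_lncRNA")
    catalog, report = build_catalog([t], FilterConfig(), {"t": -5.0}, [], [ref])
    assert catalog[0].novelty == "annotated"
    catalog2, report2 = build_catalog([t], FilterConfig(), {"t": -5.0}, [], [])
    assert catalog2[0].novelty == "novel"
    assert report.n_novel + report.n_annotated == report.n_final


def test_missing_score_policy():
    t = make_transcript("t", "chr1", "+", [(100, 300), (500, 800)],
                        coverage={"BAT": 4.0})
    with pytest.raises(KeyError):
        build_catalog([t], FilterConfig(), {}, [])
    catalog, _ = build_catalog(
        [t], FilterConfig(missing_score_policy="noncoding"), {}, []
    )
    assert len(catalog) == 1


def test_empty_input_gives_empty_catalog_not_error():
    catalog, report = build_catalog([], FilterConfig(), {}, [])
    assert catalog == [] and report.n_input == report.n_final == 0


# --- planted-truth attribution on the generator -----------------------------

def test_planted_catalog_and_filter_attribution(small_sim):
    unified = match_by_intron_chain(small_sim.assemblies)
    catalog, report = build_catalog(
        unified, FilterConfig(), small_sim.scores,
        small_sim.coding_transcripts_a, small_sim.reference_lnc_a,
    )
    assert {t.transcript_id for t in catalog} == small_sim.truth.catalog_pass
    for tid, reason in small_sim.truth.fail_reason.items():
        if reason in FILTER_NAMES:  # single-criterion decoys
            assert report.fates[tid] == reason
        else:  # genuine mRNAs fail more than one filter
            assert tid in report.fates
    annotated = {t.gene_id for t in catalog if t.novelty == "annotated"}
    assert annotated == small_sim.truth.annotated
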