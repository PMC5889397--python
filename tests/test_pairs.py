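"""Pairing, fold changes, quadrants, and the exact tests (binomial,
hypergeometric, Pearson) against brute-force oracles."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adipolnc.model import GeneRecord, GenomicInterval
from adipolnc.pairs import (
    conserved_correlation_test,
    exact_binomial_two_sided,
    expression_change_correlation,
    hypergeometric_overlap,
    log2_fold_change,
    pair_nearby,
    quadrant_classify,
    regulated,
    two_by_two_matrix,
)


def gene(gid, chrom, start, end, strand="+", biotype="protein_coding"):
    return GeneRecord(gid, GenomicInterval(chrom, start, end, strand), biotype)


# --- pairing ----------------------------------------------------------------

def test_pair_nearby_picks_nearest_by_tss():
    l = gene("L", "chr1", 1_000_000, 1_002_000, biotype="candidate")
    near = gene("g1", "chr1", 1_010_000, 1_020_000)
    far = gene("g2", "chr1", 1_080_000, 1_090_000)
    pairs = pair_nearby([l], [near, far])
    assert pairs.iloc[0].tolist() == ["L", "g1", 10_000]


def test_pair_nearby_is_strand_agnostic_for_divergent_pairs():
    l = gene("L", "chr1", 1_000_000, 1_002_000, strand="-", biotype="candidate")
    div = gene("g1", "chr1", 1_004_000, 1_020_000, strand="+")
    pairs = pair_nearby([l], [div])
    assert len(pairs) == 1 and pairs.iloc[0]["mrna_id"] == "g1"


def test_pair_nearby_respects_window():
    l = gene("L", "chr1", 1_000_000, 1_002_000, biotype="candidate")
    far = gene("g1", "chr1", 1_600_000, 1_610_000)
    assert pair_nearby([l], [far], window_bp=500_000).empty


def test_pair_nearby_random_against_brute_force():
    rng = np.random.default_rng(4)
    for _ in range(10):
        coding = [
            gene(f"g{i}", "chr1", s := int(rng.integers(0, 5_000_000)), s + 1000)
            for i in range(30)
        ]
        lncs = [
            gene(f"L{i}", "chr1", s := int(rng.integers(0, 5_000_000)), s + 500,
                 biotype="candidate")
            for i in range(10)
        ]
        pairs = pair_nearby(lncs, coding, window_bp=500_000)
        got = dict(zip(pairs["lnc_id"], pairs["mrna_id"]))
        for l in lncs:
            cands = [
                (abs(g.tss - l.tss), g.gene_id)
                for g in coding
                if abs(g.tss - l.tss) <= 500_000
            ]
            assert got.get(l.gene_id) == (min(cands)[1] if cands else None)


# --- fold changes and direction calls ---------------------------------------

def test_log2_fold_change_arithmetic_and_exclusion():
    assert log2_fold_change(5.0, 5.0, "mRNA") == pytest.approx(0.0)
    assert log2_fold_change(0.05, 0.05, "lncRNA") is None  # <=0.1 in both
    assert log2_fold_change(1.0, 2.0, "lncRNA") == pytest.approx(
        math.log2(2.1 / 1.1)
    )
    # one sample above the cutoff keeps the gene
    assert log2_fold_change(0.05, 0.5, "lncRNA") is not None


def test_log2_fold_change_antisymmetry():
    rng = np.random.default_rng(2)
    for _ in range(20):
        a, b = rng.uniform(0.2, 50, size=2)
        assert log2_fold_change(a, b, "lncRNA") == pytest.approx(
            -log2_fold_change(b, a, "lncRNA")
        )


def test_regulated_boundaries():
    assert regulated(math.log2(1.5)) == "up"  # "at least 1.5-fold" inclusive
    assert regulated(-math.log2(1.5)) == "down"
    assert regulated(0.3) == "none"
    assert regulated(-1.0) == "down"
    assert regulated(None) == "none"


def test_quadrant_classification():
    assert quadrant_classify(("up", "up"), ("up", "up")) == "coherent_up"
    assert quadrant_classify(("down", "down"), ("down", "down")) == "coherent_down"
    assert quadrant_classify(("up", "up"), ("down", "down")) == "anti"
    assert quadrant_classify(("up", "down"), ("up", "down")) == "incoherent"
    assert quadrant_classify(("up", "up"), ("up", "down")) == "incoherent"
    assert quadrant_classify(("up", "none"), ("up", "up")) is None


def test_two_by_two_matrix_examples():
    def frame(uu, ud, du, dd):
        rows = (
            [("up", "up")] * uu + [("up", "down")] * ud
            + [("down", "up")] * du + [("down", "down")] * dd
        )
        return pd.DataFrame(rows, columns=["lnc_dir", "mrna_dir"])

    assert two_by_two_matrix(frame(10, 0, 0, 10))["pct_positive"] == 100.0
    assert two_by_two_matrix(frame(0, 5, 5, 0))["pct_positive"] == 0.0
    res = two_by_two_matrix(frame(327, 52, 60, 272))
    assert res["n"] == 711 and res["n_same_direction"] == 599
    assert res["pct_positive"] == 84.2


# --- correlation of expression changes --------------------------------------

def test_expression_change_correlation_exact_cases():
    x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
    r, n = expression_change_correlation(x, 2 * x + 1)
    assert r == pytest.approx(1.0) and n == 4
    r2, _ = expression_change_correlation(x, -x)
    assert r2 == pytest.approx(-1.0)


def test_pearson_against_textbook_formula():
    rng = np.random.default_rng(11)
    for _ in range(20):
        x = pd.Series(rng.normal(size=15))
        y = pd.Series(rng.normal(size=15))
        r, _ = expression_change_correlation(x, y)
        xm, ym = x - x.mean(), y - y.mean()
        ref = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
        assert abs(r - ref) < 1e-12


# --- hypergeometric ---------------------------------------------------------

def test_hypergeometric_examples():
    universe = [f"g{i}" for i in range(10)]
    a = universe[:5]
    assert hypergeometric_overlap(a, a, universe) == pytest.approx(1 / 252)
    b_disjoint = universe[5:]
    assert hypergeometric_overlap(a, b_disjoint, universe) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        hypergeometric_overlap(["zz"], a, universe)


def _brute_hypergeom_upper(N, K, n, k):
    """P(X >= k) by enumerating all draws of size n from N."""
    universe = range(N)
    marked = set(range(K))
    hits = sum(
        1 for combo in itertools.combinations(universe, n)
        if len(marked & set(combo)) >= k
    )
    return hits / math.comb(N, n)


def test_hypergeometric_against_enumeration():
    rng = np.random.default_rng(12)
    for _ in range(15):
        N = int(rng.integers(4, 13))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        universe = [f"u{i}" for i in range(N)]
        a = universe[:K]
        b = list(rng.choice(universe, size=n, replace=False))
        k = len(set(a) & set(b))
        ours = hypergeometric_overlap(a, b, universe)
        assert ours == pytest.approx(_brute_hypergeom_upper(N, K, n, k))


# --- exact binomial ---------------------------------------------------------

def test_binomial_reproduces_conserved_pair_statistic():
    # 54 of 79 pairs with sign-conserved correlation
    assert exact_binomial_two_sided(54, 79) == pytest.approx(0.001466, abs=5e-7)


def test_binomial_trivial_cases():
    assert exact_binomial_two_sided(5, 10) == pytest.approx(1.0)
    assert exact_binomial_two_sided(8, 8) == pytest.approx(2 / 256)


def _brute_binomial_two_sided(k, n):
    pmf = [math.comb(n, j) / 2**n for j in range(n + 1)]
    return min(1.0, sum(p for p in pmf if p <= pmf[k] * (1 + 1e-9)))


def test_binomial_symmetry_and_enumeration():
    for n in range(1, 13):
        for k in range(n + 1):
            p = exact_binomial_two_sided(k, n)
            assert p == pytest.approx(exact_binomial_two_sided(n - k, n))
            assert p == pytest.approx(_brute_binomial_two_sided(k, n))
        if n % 2 == 0:
            assert exact_binomial_two_sided(n // 2, n) == pytest.approx(1.0)


def test_binomial_matches_scipy_reference():
    rng = np.random.default_rng(13)
    for _ in range(20):
        n = int(rng.integers(2, 120))
        k = int(rng.integers(0, n + 1))
        assert exact_binomial_two_sided(k, n) == pytest.approx(
            stats.binomtest(k, n, 0.5).pvalue, rel=1e-9
        )


# --- conserved correlation sign test ----------------------------------------

def test_conserved_correlation_test_counts_and_p():
    idx = [f"p{i}" for i in range(100)]
    # 79 eligible pairs (54 agreeing, 25 flipped), 21 ineligible (|R| < 0.3)
    r_a = pd.Series([0.6] * 79 + [0.1] * 21, index=idx)
    r_b = pd.Series([0.5] * 54 + [-0.5] * 25 + [0.9] * 21, index=idx)
    res = conserved_correlation_test(r_a, r_b, r_min=0.3)
    assert (res.n, res.k, res.n_pos_pos) == (79, 54, 54)
    assert res.p_value == pytest.approx(0.001466, abs=5e-7)


def test_conserved_correlation_eligibility_uses_absolute_r_by_default():
    r_a = pd.Series({"p": -0.5})
    r_b = pd.Series({"p": -0.4})
    res = conserved_correlation_test(r_a, r_b)
    assert res.n == 1 and res.k == 1 and res.n_pos_pos == 0
    signed = conserved_correlation_test(r_a, r_b, signed=True)
    assert signed.n == 0 and signed.p_value is None
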