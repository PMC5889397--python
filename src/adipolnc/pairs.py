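"""lncRNA-nearby-mRNA pair analysis.

Pairs each lncRNA with its nearest coding gene (TSS-to-TSS, strand-agnostic
so divergent promoter pairs are captured), computes pseudocounted log2 fold
changes under the class-specific low-expression exclusion, calls regulation
at the 1.5-fold threshold, classifies pair coherence across two adipogenesis
systems into four quadrants, tabulates single-contrast 2x2 direction
matrices, and tests whether lncRNA-mRNA correlation signs are preserved
across species with an exact two-sided binomial sign test.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExpressionMatrix, GeneRecord
from .specificity import pct

QUADRANTS = ("coherent_up", "coherent_down", "anti", "incoherent")

DETECT_CUTOFF = {"lncRNA": 0.1, "mRNA": 1.0}


def pair_nearby(
    lnc_genes: Sequence[GeneRecord],
    coding_genes: Sequence[GeneRecord],
    window_bp: int = 500_000,
) -> pd.DataFrame:
    """Pair each lncRNA with the single nearest coding gene by TSS distance.

    Strand-agnostic and window-limited; lncRNAs with no coding gene within
    the window yield no pair. Distance ties break on the smaller gene id.
    """
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in coding_genes:
        by_chrom.setdefault(g.span.chrom, []).append(g)
    rows = []
    for l in lnc_genes:
        best: tuple[int, str] | None = None
        for g in by_chrom.get(l.span.chrom, ()):
            d = abs(g.tss - l.tss)
            if d > window_bp:
                continue
            cand = (d, g.gene_id)
            if best is None or cand < best:
                best = cand
        if best is not None:
            rows.append({"lnc_id": l.gene_id, "mrna_id": best[1], "distance": best[0]})
    return pd.DataFrame(rows, columns=["lnc_id", "mrna_id", "distance"])


def log2_fold_change(
    pre: float,
    post: float,
    gene_class: str,
    pseudocount: float | None = None,
) -> float | None:
    """log2((post + c) / (pre + c)); None when the gene fails the
    low-expression exclusion (at or below its class cutoff in BOTH samples).

    The pseudocount defaults to the class detectability cutoff (0.1 for
    lncRNA, 1.0 for mRNA).
    """
    cutoff = DETECT_CUTOFF[gene_class]
    if pre <= cutoff and post <= cutoff:
        return None
    c = cutoff if pseudocount is None else pseudocount
    return math.log2((post + c) / (pre + c))


def fold_change_table(
    pre: ExpressionMatrix, post: ExpressionMatrix, sample: str | int = 0
) -> pd.Series:
    """Vectorised log2 fold changes for every gene shared by two matrices;
    excluded genes get NaN."""
    if pre.classes is None:
        raise ValueError("fold changes need gene class labels")
    col_pre = pre.values.iloc[:, sample] if isinstance(sample, int) else pre.values[sample]
    col_post = post.values.iloc[:, sample] if isinstance(sample, int) else post.values[sample]
    genes = col_pre.index.intersection(col_post.index)
    out = {}
    for g in genes:
        out[g] = log2_fold_change(
            float(col_pre[g]), float(col_post[g]), str(pre.classes[g])
        )
    return pd.Series(out, dtype=float)


def regulated(fc: float | None, min_fold: float = 1.5) -> str:
    """Direction call at the fold threshold, boundary inclusive."""
    if fc is None or (isinstance(fc, float) and math.isnan(fc)):
        return "none"
    thr = math.log2(min_fold) - 1e-12
    if fc >= thr:
        return "up"
    if fc <= -thr:
        return "down"
    return "none"


def quadrant_classify(
    lnc_dirs: tuple[str, str], mrna_dirs: tuple[str, str]
) -> str | None:
    """Coherence class of one pair given (dataset1, dataset2) directions.

    Requires both members regulated in both datasets (else None):
    coherent_up = all four up; coherent_down = all four down; anti = lncRNA
    and mRNA move oppositely within each dataset, with the lncRNA direction
    consistent across datasets; anything else is incoherent.
    """
    dirs = [*lnc_dirs, *mrna_dirs]
    if any(d not in ("up", "down") for d in dirs):
        return None
    if all(d == "up" for d in dirs):
        return "coherent_up"
    if all(d == "down" for d in dirs):
        return "coherent_down"
    anti_each = lnc_dirs[0] != mrna_dirs[0] and lnc_dirs[1] != mrna_dirs[1]
    if anti_each and lnc_dirs[0] == lnc_dirs[1]:
        return "anti"
    return "incoherent"


def classify_pairs(
    pairs: pd.DataFrame,
    fc_lnc: Mapping[str, pd.Series],
    fc_mrna: Mapping[str, pd.Series],
    min_fold: float = 1.5,
) -> pd.DataFrame:
    """Quadrant class per pair across two named datasets.

    ``fc_lnc``/``fc_mrna`` map dataset name -> per-gene log2 FC Series.
    Pairs failing the regulation precondition get class None.
    """
    ds = list(fc_lnc)
    if len(ds) != 2 or list(fc_mrna) != ds:
        raise ValueError("exactly two datasets with matching names required")
    out = pairs.copy()
    classes = []
    for _, row in pairs.iterrows():
        ldirs = tuple(
            regulated(fc_lnc[d].get(row["lnc_id"], float("nan")), min_fold)
            for d in ds
        )
        mdirs = tuple(
            regulated(fc_mrna[d].get(row["mrna_id"], float("nan")), min_fold)
            for d in ds
        )
        classes.append(quadrant_classify(ldirs, mdirs))
    out["quadrant"] = classes
    return out


def quadrant_counts(classified: pd.DataFrame) -> dict[str, int]:
    counts = {q: 0 for q in QUADRANTS}
    for q in classified["quadrant"].dropna():
        counts[q] += 1
    return counts


def two_by_two_matrix(directions: pd.DataFrame) -> dict:
    """Single-contrast 2x2 pair matrix.

    ``directions`` needs columns lnc_dir and mrna_dir in {up, down}; other
    pairs are ignored. Returns the four cell counts and the positively
    correlated (same-direction) fraction as a percentage (1 dp).
    """
    cells = {("up", "up"): 0, ("up", "down"): 0, ("down", "up"): 0, ("down", "down"): 0}
    for _, row in directions.iterrows():
        key = (row["lnc_dir"], row["mrna_dir"])
        if key in cells:
            cells[key] += 1
    total = sum(cells.values())
    same = cells[("up", "up")] + cells[("down", "down")]
    return {
        "cells": cells,
        "n": total,
        "n_same_direction": same,
        "pct_positive": pct(same, total, decimals=1) if total else 0.0,
    }


def expression_change_correlation(
    fcs_x: pd.Series, fcs_y: pd.Series, min_genes: int = 3
) -> tuple[float, int]:
    """Pearson R of per-gene log2 fold changes shared by two datasets.

    Returns (R, n shared genes); R is NaN when either vector has zero
    variance."""
    shared = fcs_x.dropna().index.intersection(fcs_y.dropna().index)
    if len(shared) < min_genes:
        raise ValueError(f"need >={min_genes} shared genes, got {len(shared)}")
    x = fcs_x.loc[shared].to_numpy(dtype=float)
    y = fcs_y.loc[shared].to_numpy(dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan"), len(shared)
    return float(stats.pearsonr(x, y).statistic), len(shared)


def hypergeometric_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> float:
    """Exact upper-tail P(X >= |A intersect B|) for X ~ Hypergeom(N, |A|, |B|)."""
    universe = set(universe)
    a = set(set_a)
    b = set(set_b)
    if not a <= universe or not b <= universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(a), len(b)))


def exact_binomial_two_sided(k: int, n: int, p: float = 0.5) -> float:
    """Exact two-sided binomial p-value by the minimum-likelihood method:
    the sum of P(j) over all outcomes j no more probable than the observed k."""
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    js = np.arange(n + 1)
    pmf = stats.binom.pmf(js, n, p)
    p_obs = pmf[k]
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-9)].sum()))


@dataclass
class ConservedCorrelationResult:
    """Outcome of the cross-species correlation sign test."""

    n: int
    k: int  # sign-agreeing pairs
    n_pos_pos: int  # pairs positive in both species
    p_value: float | None

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError("require 0 <= k <= n")


def conserved_correlation_test(
    r_a: pd.Series,
    r_b: pd.Series,
    r_min: float = 0.3,
    signed: bool = False,
) -> ConservedCorrelationResult:
    """Binomial sign test for preserved lncRNA-mRNA correlation.

    Eligible pairs have |R| >= r_min in both species (or signed R >= r_min
    with ``signed``); k counts pairs whose correlation signs agree; the
    p-value is the exact two-sided binomial test at null 0.5. n = 0 yields
    an undefined (None) p-value.
    """
    shared = r_a.dropna().index.intersection(r_b.dropna().index)
    a = r_a.loc[shared]
    b = r_b.loc[shared]
    if signed:
        eligible = (a >= r_min) & (b >= r_min)
    else:
        eligible = (a.abs() >= r_min) & (b.abs() >= r_min)
    a = a[eligible]
    b = b[eligible]
    n = int(eligible.sum())
    k = int((np.sign(a) == np.sign(b)).sum())
    n_pos_pos = int(((a > 0) & (b > 0)).sum())
    p = exact_binomial_two_sided(k, n) if n > 0 else None
    return ConservedCorrelationResult(n=n, k=k, n_pos_pos=n_pos_pos, p_value=p)


def pair_expression_correlations(
    pairs: pd.DataFrame, m: ExpressionMatrix
) -> pd.Series:
    """Pearson R between each pair's expression vectors across samples."""
    out = {}
    vals = m.values
    for _, row in pairs.iterrows():
        l, g = row["lnc_id"], row["mrna_id"]
        if l not in vals.index or g not in vals.index:
            out[(l, g)] = float("nan")
            continue
        x = vals.loc[l].to_numpy(dtype=float)
        y = vals.loc[g].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            out[(l, g)] = float("nan")
        else:
            out[(l, g)] = float(stats.pearsonr(x, y).statistic)
    return pd.Series(out, dtype=float)
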