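"""Fractional-expression tissue specificity.

A gene's specificity score in a tissue is its FPKM there divided by its
summed FPKM across the whole tissue panel; the largest of these fractions
(the maximal fractional expression) decides whether the gene is called
tissue-specific at a given threshold. Detectability, depot-overlap (Venn)
tabulation, expressed-tissue counts, pairwise tissue correlations and a
rank-sum distribution comparison live here too.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import ExpressionMatrix

log = logging.getLogger(__name__)


def pct(k: float, n: float, decimals: int = 2) -> float:
    """Percentage reported to ``decimals`` places, round-half-to-even."""
    if n == 0:
        raise ValueError("percentage undefined for zero denominator")
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(100 * k / n).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass
class SpecificityProfile:
    """Per-gene fractional expression across the tissue panel.

    Genes with zero total expression have undefined fractions (NaN rows)
    and can never be called specific.
    """

    fractions: pd.DataFrame  # genes x tissues, rows sum to 1 for expressed genes
    max_fraction: pd.Series
    argmax_tissue: pd.Series  # ties broken by first tissue in column order

    @property
    def expressed(self) -> pd.Index:
        return self.max_fraction.dropna().index


def fractional_expression(m: ExpressionMatrix) -> SpecificityProfile:
    """s_{g,t} = FPKM_{g,t} / sum_t' FPKM_{g,t'} per gene."""
    if len(m.samples) < 2:
        raise ValueError("specificity needs >=2 tissues")
    totals = m.values.sum(axis=1)
    fractions = m.values.div(totals, axis=0)
    fractions[totals == 0] = np.nan
    max_fraction = fractions.max(axis=1)
    # idxmax takes the first column on ties, which is the documented tie-break
    argmax = pd.Series(None, index=fractions.index, dtype=object)
    expressed_rows = fractions.index[totals > 0]
    if len(expressed_rows):
        argmax.loc[expressed_rows] = fractions.loc[expressed_rows].idxmax(axis=1)
    n_ties = int(
        (fractions.eq(fractions.max(axis=1), axis=0).sum(axis=1) > 1).sum()
    )
    if n_ties:
        log.info("argmax ties for %d genes broken by tissue column order", n_ties)
    return SpecificityProfile(fractions, max_fraction, argmax)


def classify_specific(
    profile: SpecificityProfile,
    threshold: float = 0.1,
    restrict_to: Iterable[str] | None = None,
) -> pd.Series:
    """Assign each gene its specific tissue, or None.

    A gene is specific to its argmax tissue iff max_fraction is strictly
    above ``threshold``. With ``restrict_to`` (e.g. the three adipose
    depots) a gene only counts if its argmax tissue is in the subset.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    passing = profile.max_fraction > threshold
    tissue = profile.argmax_tissue.where(passing, other=None)
    if restrict_to is not None:
        allowed = set(restrict_to)
        tissue = tissue.where(tissue.isin(allowed), other=None)
    return tissue


def threshold_sweep(
    profile: SpecificityProfile,
    classes: pd.Series,
    thresholds: Sequence[float] = tuple(np.arange(0.10, 0.501, 0.05)),
    restrict_to: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Tissue-specific counts and percentages per threshold, split by gene class.

    Percent denominators are the expressed genes of each class.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    rows = []
    for thr in thresholds:
        specific = classify_specific(profile, thr, restrict_to)
        for cls in ("lncRNA", "mRNA"):
            genes = classes[classes == cls].index.intersection(profile.expressed)
            n_specific = int(specific.loc[genes].notna().sum())
            rows.append(
                {
                    "threshold": round(thr, 4),
                    "class": cls,
                    "n_specific": n_specific,
                    "n_expressed": len(genes),
                    "pct_specific": pct(n_specific, len(genes)) if len(genes) else 0.0,
                }
            )
    return pd.DataFrame(rows)


def detectability(
    m: ExpressionMatrix,
    lnc_cutoff: float = 0.1,
    mrna_cutoff: float = 1.0,
    samples: Sequence[str] | None = None,
) -> dict[str, frozenset[str]]:
    """Per-gene set of samples where the gene is detected (FPKM strictly
    above its class cutoff). Pass equal cutoffs for the standardized-cutoff
    variant."""
    if lnc_cutoff < 0 or mrna_cutoff < 0:
        raise ValueError("cutoffs must be >= 0")
    if m.classes is None:
        raise ValueError("detectability needs gene class labels")
    cols = list(samples) if samples is not None else m.samples
    sub = m.values[cols]
    cutoff = m.classes.map({"lncRNA": lnc_cutoff, "mRNA": mrna_cutoff})
    detected = sub.gt(cutoff, axis=0)
    return {
        g: frozenset(detected.columns[detected.loc[g]]) for g in detected.index
    }


def depot_overlap(
    detected: Mapping[str, frozenset[str]], depots: Sequence[str]
) -> dict:
    """Venn-region counts over exactly three depots.

    Returns the 7 region counts (keyed by sorted tuples of depot names),
    the union size, and the count/percentage of genes detected in exactly
    one depot.
    """
    if len(depots) != 3 or len(set(depots)) != 3:
        raise ValueError("depot_overlap requires exactly 3 distinct depot labels")
    depot_set = set(depots)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, 4):
        for combo in itertools.combinations(sorted(depots), r):
            regions[combo] = 0
    exactly_one = 0
    union = 0
    for gene, samples in detected.items():
        members = tuple(sorted(samples & depot_set))
        if not members:
            continue
        union += 1
        regions[members] += 1
        if len(members) == 1:
            exactly_one += 1
    return {
        "regions": regions,
        "union": union,
        "exactly_one": exactly_one,
        "pct_exactly_one": pct(exactly_one, union) if union else 0.0,
    }


def tissue_counts(m: ExpressionMatrix, cutoff: float = 0.1) -> pd.Series:
    """Per-gene number of tissues with FPKM strictly above ``cutoff``."""
    return m.values.gt(cutoff).sum(axis=1)


def pairwise_tissue_correlations(
    m: ExpressionMatrix, genes: Iterable[str] | None = None
) -> pd.DataFrame:
    """Pearson correlation per unordered tissue pair over a gene subset.

    22 tissues yield 231 values. Tissue columns with zero variance over
    the subset make their pairs undefined; those pairs are excluded and
    logged.
    """
    sub = m.values.loc[list(genes)] if genes is not None else m.values
    if len(sub) < 2:
        raise ValueError("need >=2 genes to correlate tissues")
    arr = sub.to_numpy(dtype=float)
    sds = arr.std(axis=0)
    cols = list(sub.columns)
    dropped = [c for c, s in zip(cols, sds) if s == 0]
    if dropped:
        log.warning("zero-variance tissues excluded from pairwise r: %s", dropped)
    rows = []
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(arr, rowvar=False)
    for i, j in itertools.combinations(range(len(cols)), 2):
        if sds[i] == 0 or sds[j] == 0:
            continue
        rows.append({"tissue_a": cols[i], "tissue_b": cols[j], "r": corr[i, j]})
    return pd.DataFrame(rows)


def compare_distributions(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Exact by full enumeration of group assignments when the combined sample
    size is <= 12 (ties handled by the half-count convention); otherwise the
    normal approximation with tie correction.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    if not x or not y:
        raise ValueError("both samples must be non-empty")
    if len(x) + len(y) <= 12:
        return _exact_rank_sum(x, y)
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    )


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    u = 0.0
    for a in x:
        for b in y:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def _exact_rank_sum(x: list[float], y: list[float]) -> float:
    pooled = x + y
    n1 = len(x)
    idx = range(len(pooled))
    mu = n1 * len(y) / 2.0
    obs_dev = abs(_u_statistic(x, y) - mu)
    total = 0
    extreme = 0
    for combo in itertools.combinations(idx, n1):
        chosen = set(combo)
        gx = [pooled[i] for i in idx if i in chosen]
        gy = [pooled[i] for i in idx if i not in chosen]
        total += 1
        if abs(_u_statistic(gx, gy) - mu) >= obs_dev - 1e-12:
            extreme += 1
    return extreme / total
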