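"""Guilt-by-association functional inference.

Infers candidate functions for a query lncRNA from the annotated functions
of strongly co-expressed protein-coding genes: partners are coding genes
whose expression correlates with the query at Pearson R >= 0.7 (signed,
positive) across the sample panel; the partner list is then tested for
over-representation in user-supplied gene sets (GMT) with an exact
hypergeometric upper-tail test, Benjamini-Hochberg adjusted.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import ExpressionMatrix, GeneSetCollection
from .pairs import hypergeometric_overlap


def coexpressed_partners(
    query: str, m: ExpressionMatrix, r_min: float = 0.7
) -> pd.DataFrame:
    """Coding genes positively correlated with the query lncRNA.

    Returns a gene/R table (R >= r_min, signed). Genes with zero variance
    are skipped; a zero-variance query is an error since its correlation is
    undefined.
    """
    if len(m.samples) < 3:
        raise ValueError("need >=3 samples to correlate")
    if query not in m.values.index:
        raise KeyError(f"query {query!r} not in matrix")
    if m.classes is None:
        raise ValueError("partner selection needs gene class labels")
    q = m.values.loc[query].to_numpy(dtype=float)
    if q.std() == 0:
        raise ValueError(f"correlation undefined: query {query!r} has zero variance")
    coding = m.classes[m.classes == "mRNA"].index
    sub = m.values.loc[coding]
    arr = sub.to_numpy(dtype=float)
    sds = arr.std(axis=1)
    qc = q - q.mean()
    centered = arr - arr.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = centered @ qc / (np.sqrt((centered**2).sum(axis=1)) * np.sqrt((qc**2).sum()))
    keep = (sds > 0) & (r >= r_min)
    out = pd.DataFrame({"gene_id": sub.index[keep], "r": r[keep]})
    return out.sort_values("r", ascending=False).reset_index(drop=True)


def ora(
    selected: list[str] | set[str],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
    min_set_overlap: int = 3,
    adjust: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each gene set.

    Sets and selection are intersected with the universe; sets overlapping
    the selection by fewer than ``min_set_overlap`` genes are dropped before
    multiple testing. Returns one row per surviving set sorted by ascending
    p, with BH q-values (set ``adjust=False`` for raw-p mode).
    """
    if universe is None:
        universe = collection.universe
    if not universe:
        raise ValueError("ORA needs a non-empty universe")
    universe = set(universe)
    selected = set(selected) & universe
    rows = []
    for name, members in collection.sets.items():
        members = set(members) & universe
        if not members:
            continue
        overlap = len(members & selected)
        if overlap < min_set_overlap:
            continue
        p = hypergeometric_overlap(members, selected, universe)
        rows.append(
            {
                "set": name,
                "overlap": overlap,
                "set_size": len(members),
                "n_selected": len(selected),
                "universe_size": len(universe),
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["set", "overlap", "set_size", "n_selected", "universe_size", "p_value"],
    )
    if df.empty:
        df["q_value"] = pd.Series(dtype=float)
        return df
    if adjust:
        df["q_value"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        df["q_value"] = df["p_value"]
    return df.sort_values(["p_value", "set"]).reset_index(drop=True)
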