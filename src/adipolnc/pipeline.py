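"""End-to-end orchestration on generated data.

``run_all`` executes simulate -> build-catalog -> specificity -> conserve ->
pairs -> guilt on a synthetic fixture set, writes machine-readable TSV/JSON
outputs plus a checksum manifest, and returns the in-memory results. With a
fixed seed reruns are byte-identical (no timestamps anywhere).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .catalog import FilterConfig, build_catalog, match_by_intron_chain
from .coexpression import coexpressed_partners, ora
from .config import AnalysisConfig
from .conservation import conserved_catalog, conserved_ids
from .io_formats import write_bed, write_tsv_report
from .model import GeneRecord
from .pairs import (
    classify_pairs,
    conserved_correlation_test,
    fold_change_table,
    pair_expression_correlations,
    pair_nearby,
    quadrant_counts,
    regulated,
    two_by_two_matrix,
)
from .specificity import (
    classify_specific,
    depot_overlap,
    detectability,
    fractional_expression,
    pairwise_tissue_correlations,
    threshold_sweep,
    tissue_counts,
)
from .synthetic import (
    DEPOTS,
    simulate_cold_contrast,
    simulate_coexpression_panel,
    simulate_correlation_panels,
    simulate_expression_panel,
    simulate_gene_models,
    simulate_timecourse,
)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: AnalysisConfig, outdir: str | Path | None = None) -> dict:
    """Run the full synthetic end-to-end analysis; return a results dict.

    When ``outdir`` is given (or set in the config) every stage writes its
    table there and a ``manifest.json`` records sha256 checksums of all
    outputs together with the package version and a config hash.
    """
    out = Path(outdir) if outdir is not None else Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # --- simulate -----------------------------------------------------------
    sim = simulate_gene_models(config.simulation)
    panel = simulate_expression_panel(config.simulation, sim)
    timecourse = simulate_timecourse(config.simulation, sim)
    tn, cold = simulate_cold_contrast(config.simulation, sim)
    corr_a, corr_b = simulate_correlation_panels(config.simulation, sim)
    coexpr, query, planted_partners, gene_sets = simulate_coexpression_panel(
        config.simulation, sim
    )
    results["sim"] = sim

    # --- build-catalog ------------------------------------------------------
    unified = match_by_intron_chain(sim.assemblies)
    fcfg = FilterConfig(
        min_coverage=config.min_coverage,
        min_length_bp=config.min_length,
        min_exons=config.min_exons,
    )
    catalog, report = build_catalog(
        unified, fcfg, sim.scores, sim.coding_transcripts_a, sim.reference_lnc_a
    )
    results["catalog"] = catalog
    results["catalog_report"] = report
    write_bed(catalog, out / "catalog.bed")
    write_tsv_report(report.to_frame(), out / "catalog_report.tsv")

    # --- specificity --------------------------------------------------------
    profile = fractional_expression(panel)
    specific = classify_specific(profile, config.specificity_threshold)
    sweep = threshold_sweep(profile, panel.classes, config.sweep_thresholds)
    adipose_sweep = threshold_sweep(
        profile, panel.classes, config.sweep_thresholds, restrict_to=DEPOTS
    )
    detected = detectability(
        panel.of_class("lncRNA"), config.lnc_detect, config.mrna_detect,
        samples=list(DEPOTS),
    )
    venn = depot_overlap(detected, DEPOTS)
    counts = tissue_counts(panel, cutoff=config.lnc_detect)
    results.update(
        profile=profile, specific=specific, sweep=sweep,
        adipose_sweep=adipose_sweep, depot_venn=venn, tissue_counts=counts,
    )
    write_tsv_report(sweep, out / "specificity_sweep.tsv")
    write_tsv_report(adipose_sweep, out / "adipose_sweep.tsv")
    spec_df = pd.DataFrame(
        {
            "gene_id": specific.index,
            "specific_tissue": [t if t is not None else "" for t in specific],
            "max_fraction": profile.max_fraction.reindex(specific.index),
        }
    )
    write_tsv_report(spec_df, out / "specific_genes.tsv")

    # --- conserve -----------------------------------------------------------
    calls = conserved_catalog(
        sim.lnc_genes_a, sim.lnc_genes_b, sim.genes_a, sim.genes_b, sim.orth,
        window_bp=config.window_bp, min_shared=config.min_shared_synteny,
    )
    results["conservation_calls"] = calls
    write_tsv_report(
        pd.DataFrame(
            [
                {
                    "lnc_id": c.lnc_id,
                    "partner": c.partner or "",
                    "evidence": c.evidence if c.partner else "",
                    "shared_flanking": c.shared_flanking,
                }
                for c in calls
            ]
        ),
        out / "conservation_calls.tsv",
    )
    conserved = conserved_ids(calls)

    # conserved lncRNAs are the broadly expressed class: pairwise tissue r
    lnc_panel = panel.of_class("lncRNA")
    r_cons = pairwise_tissue_correlations(lnc_panel, genes=sorted(conserved))
    noncons = sorted(set(lnc_panel.genes) - conserved)
    r_non = pairwise_tissue_correlations(lnc_panel, genes=noncons)
    results["median_r_conserved"] = float(r_cons["r"].median())
    results["median_r_nonconserved"] = float(r_non["r"].median())

    # --- pairs --------------------------------------------------------------
    catalog_gene_ids = {t.gene_id for t in catalog}
    lnc_records = [g for g in sim.lnc_genes_a if g.gene_id in catalog_gene_ids]
    pairs = pair_nearby(lnc_records, sim.genes_a, config.window_bp)
    results["pairs"] = pairs

    fc = {
        ds: fold_change_table(pre, post)
        for ds, (pre, post) in timecourse.items()
    }
    classified = classify_pairs(pairs, fc, fc, min_fold=config.min_fold)
    results["classified_pairs"] = classified
    results["quadrant_counts"] = quadrant_counts(classified)
    write_tsv_report(classified, out / "pair_quadrants.tsv")

    cold_fc = fold_change_table(tn, cold)
    dirs = []
    for _, row in pairs.iterrows():
        ld = regulated(cold_fc.get(row["lnc_id"], float("nan")), config.min_fold)
        md = regulated(cold_fc.get(row["mrna_id"], float("nan")), config.min_fold)
        if ld != "none" and md != "none":
            dirs.append({"lnc_dir": ld, "mrna_dir": md})
    results["cold_matrix"] = two_by_two_matrix(pd.DataFrame(dirs))

    # cross-species correlation sign conservation: the species-B side of a
    # conserved pair is the syntenic partner lncRNA together with the
    # ortholog of the species-A mRNA
    partner_of = {c.lnc_id: c.partner for c in calls if c.partner}
    pair_r_a = pair_expression_correlations(pairs, corr_a)
    lnc_to_mrna = dict(zip(pairs["lnc_id"], pairs["mrna_id"]))
    b_rows = []
    for lnc in sorted(conserved):
        if lnc not in lnc_to_mrna or lnc not in partner_of:
            continue
        mrna_b = sim.orth.to_b(lnc_to_mrna[lnc])
        if mrna_b is None:
            continue
        b_rows.append(
            {"a_lnc": lnc, "lnc_id": partner_of[lnc], "mrna_id": mrna_b}
        )
    b_frame = pd.DataFrame(b_rows, columns=["a_lnc", "lnc_id", "mrna_id"])
    pair_r_b = pair_expression_correlations(b_frame, corr_b)
    r_a_vals, r_b_vals = {}, {}
    for _, row in b_frame.iterrows():
        lnc = row["a_lnc"]
        r_a_vals[lnc] = pair_r_a.get((lnc, lnc_to_mrna[lnc]), float("nan"))
        r_b_vals[lnc] = pair_r_b.get((row["lnc_id"], row["mrna_id"]), float("nan"))
    sign_test = conserved_correlation_test(
        pd.Series(r_a_vals, dtype=float), pd.Series(r_b_vals, dtype=float),
        r_min=config.r_min_pairs,
    )
    results["conserved_correlation"] = sign_test

    # --- guilt --------------------------------------------------------------
    partners = coexpressed_partners(query, coexpr, r_min=config.r_min_guilt)
    enrich = ora(
        set(partners["gene_id"]), gene_sets,
        min_set_overlap=config.min_set_overlap,
    )
    results["guilt_query"] = query
    results["guilt_partners"] = partners
    results["guilt_planted_partners"] = planted_partners
    results["enrichment"] = enrich
    write_tsv_report(partners, out / "guilt_partners.tsv")
    write_tsv_report(enrich, out / "guilt_enrichment.tsv")

    # --- summary + manifest -------------------------------------------------
    summary = {
        "version": __version__,
        "seed": config.seed,
        "catalog_size": len(catalog),
        "n_novel": report.n_novel,
        "n_annotated": report.n_annotated,
        "n_specific": int(specific.notna().sum()),
        "n_conserved": len(conserved),
        "n_pairs": len(pairs),
        "quadrants": results["quadrant_counts"],
        "cold_pct_positive": results["cold_matrix"]["pct_positive"],
        "sign_test": {
            "n": sign_test.n, "k": sign_test.k, "p": sign_test.p_value,
        },
    }
    with open(out / "summary.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["summary"] = summary

    config_blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    manifest = {
        "version": __version__,
        "config_sha256": hashlib.sha256(config_blob).hexdigest(),
        "files": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    results["manifest"] = manifest
    return results
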