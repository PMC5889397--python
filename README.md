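# adipolnc

Construction and characterisation of a human adipose long non-coding RNA
(lncRNA) catalog, as a tested, reusable Python pipeline.

Most lncRNAs are lowly expressed, highly tissue-specific, and poorly
conserved in primary sequence, so reference annotations systematically miss
the lncRNAs active in any one tissue — including the brown (BAT) and white
(oWAT, sWAT) adipose depots that matter for obesity and thermogenesis
research. `adipolnc` implements the downstream computational analyses used
to build and characterise such a catalog from de novo assembled
transcripts, for computational biologists working with bulk RNA-seq of
adipose (or any other) tissue:

1. **Catalog building** (`adipolnc.catalog`) — a five-criterion filter
   cascade over assembled transcripts: read coverage ≥ 3 in at least one
   tissue, length ≥ 200 bp, ≥ 2 exons, low coding potential (precomputed
   PhyloCSF-style score ≤ 0), and no same-strand exonic overlap with known
   coding genes; survivors are split into *novel* vs *annotated* against a
   reference lncRNA annotation. Per-tissue assemblies are reconciled by
   intron-chain matching.
2. **Tissue specificity** (`adipolnc.specificity`) — the fractional
   expression score
   s<sub>g,t</sub> = FPKM<sub>g,t</sub> / Σ<sub>t′</sub> FPKM<sub>g,t′</sub>
   over a 22-tissue panel; a gene is specific to its argmax tissue when the
   maximal fraction exceeds a threshold (default 0.1, strict). Includes
   threshold sweeps, class-specific detectability (FPKM > 0.1 for lncRNA,
   > 1.0 for mRNA), three-depot Venn bookkeeping, expressed-tissue counts,
   pairwise tissue correlations, and a Mann–Whitney rank-sum comparison.
3. **Conservation by synteny** (`adipolnc.conservation`) — a lncRNA in one
   species is called conserved when a lncRNA in the other species has the
   same relative order of flanking protein-coding genes (±500 kb, same
   strand, mapped through a coding-gene ortholog table); an external
   sequence-similarity table can be merged in ("either criterion").
4. **lncRNA–mRNA pair analysis** (`adipolnc.pairs`) — each lncRNA is
   paired with its nearest coding gene by TSS distance (strand-agnostic,
   capturing divergent promoter pairs); pseudocounted log2 fold changes
   under the class-specific low-expression exclusion; regulation calls at
   ≥ 1.5-fold; coherence quadrants (coherent-up / coherent-down / anti /
   incoherent) across two adipogenesis systems; single-contrast 2×2
   direction matrices; exact hypergeometric overlap tests; and an exact
   two-sided binomial sign test (null p = 0.5, minimum-likelihood method)
   for whether pair correlation signs are preserved across species.
5. **Guilt-by-association** (`adipolnc.coexpression`) — partners of a
   query lncRNA at Pearson R ≥ 0.7, tested for over-representation against
   GMT gene sets (hypergeometric upper tail, Benjamini–Hochberg adjusted,
   sets with overlap < 3 dropped).

A first-class synthetic-data generator (`adipolnc.synthetic`) produces
two-species toy genomes, expression panels, time courses and cold-exposure
contrasts with planted ground truth, so every stage is testable end-to-end
without any download.

## Worked example

```python
from adipolnc.config import AnalysisConfig
from adipolnc.pipeline import run_all

results = run_all(AnalysisConfig(seed=1), "demo_out")
print(results["summary"])
```

prints (abridged):

```
catalog_size   120      # all 120 planted lncRNAs pass the cascade; decoys removed
n_novel        78       # no exonic overlap with the reference lncRNA annotation
n_annotated    42
n_conserved    12       # syntenic partners recovered, = the planted 10%
n_pairs        102      # lncRNAs with a coding gene within 500 kb
quadrants      {'coherent_up': 41, 'coherent_down': 21, 'anti': 8, 'incoherent': 20}
cold_pct_positive  84.0 # same-direction lncRNA–mRNA pairs upon cold exposure
sign_test      {'n': 12, 'k': 9, 'p': 0.146}
```

The quadrant counts recover the planted 43/22/8/20 classes up to the
default measurement noise (exactly, when the generator noise is switched
off), and the sign test reports the planted 9-of-12 cross-species
sign-agreement with its exact binomial p-value. The guilt-by-association
stage ranks the planted co-expression module first
(`PLANTED_MODULE, overlap 10/18, p = 8.6e-08, q = 4.3e-07`).

The same stages are available from the shell:

```bash
adipolnc simulate --out fixtures/
adipolnc build-catalog --assemblies BAT=fixtures/assembly_BAT.gtf,... \
    --coding-ann fixtures/coding_A.gtf --ref-lnc fixtures/reference_lnc_A.gtf \
    --scores fixtures/scores.tsv --out catalog.bed --report report.tsv
adipolnc run-all --seed 1 --out demo_out/
```

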