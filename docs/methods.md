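# Methods

This note documents the models and conventions implemented in `adipolnc`,
what the synthetic-data generator does and does not emulate, and the design
choices made where the procedure was genuinely open.

## The catalog filter cascade

Assembled transcripts from each tissue are first reconciled by
**intron-chain matching**: transcripts with identical ordered intron
coordinates on the same chromosome and strand are treated as one molecule
assembled in several tissues (single-exon models match only on their exact
span, since they have no chain). Coverage and FPKM are then keyed per
tissue on the unified model, which is what makes the "coverage ≥ 3 in at
least one tissue" criterion evaluable.

Five conjunctive filters follow, all boundaries inclusive (≥):

| filter | default | note |
|---|---|---|
| read coverage | ≥ 3 in ≥ 1 tissue | per-transcript assembler coverage; a missing tissue counts as 0 |
| length | ≥ 200 bp | sum of exon lengths (mature transcript) |
| exon count | ≥ 2 | guards against single-exon assembly artifacts |
| coding potential | score ≤ 0 | consumed as a precomputed per-transcript table (PhyloCSF-style, higher = more coding). Recomputing such scores needs whole-genome alignments, so they are an input; `longest_orf` is provided as an auxiliary descriptor |
| sense overlap | none | ≥ 1 bp exonic overlap with a coding exon on the same chromosome *and strand*; intronic overlap does not count |

Because the filters are conjunctive, the final catalog is invariant under
filter order; the per-transcript removal attribution follows cascade order
and is only unambiguous for transcripts failing a single criterion (the
report records the first failing filter). Survivors are labelled
**annotated** when ≥ 1 bp of same-strand exonic overlap with the reference
lncRNA annotation exists, else **novel**; a splice-junction-sharing
alternative was considered and rejected as stricter than the stated
"referencing against" an annotation warrants, but the overlap predicate is
isolated in one place (`ExonOverlapIndex`) should it need changing.

## Fractional tissue specificity

For gene *g* and tissue *t*, the specificity score is
`s[g,t] = FPKM[g,t] / Σ_t' FPKM[g,t']`; the largest score is the *maximal
fractional expression* and its tissue the candidate specific tissue. A gene
is called specific when the maximal fraction is **strictly above** the
threshold (default 0.1) — "above a threshold" is read as `>`, and the same
strict reading applies to detectability cutoffs (`FPKM > 0.1` lncRNA,
`> 1.0` mRNA). Genes with zero total expression have undefined fractions
and are excluded rather than assigned uniform scores (0/0 is undefined and
real analyses pre-filter undetected genes). Ties for the argmax tissue are
broken by first tissue in column order and logged. Percentages are reported
to two decimals with round-half-to-even.

## Synteny-based conservation

For each lncRNA, the context is the ordered list of protein-coding genes
within ±500 kb of its span (span-gap distance, boundary inclusive) on its
chromosome **and strand**. Two lncRNAs match when, after restricting each
context to genes whose ortholog appears in the other context:

- at least `min_shared = 2` genes remain — a single shared gene cannot
  establish *relative order*, so 2 is the weakest meaningful reading, and
  it is configurable;
- the shared genes, read along the chromosome with the lncRNA inserted at
  its own position, appear in identical order (whole-context reversal is
  accepted when the two lncRNAs sit on opposite assembly strands, since
  synteny blocks invert between assemblies);
- upstream/downstream sidedness relative to the lncRNA is preserved
  (relaxable by flag).

Many-to-many ortholog rows are resolved one-to-one by keeping the
first-listed pair (deterministic; discards logged). Each lncRNA yields at
most one call: most shared flanking orthologs first, then smallest
nearest-shared-flank offset discrepancy, then partner id. lncRNAs in gene
deserts (empty context) are unresolvable by synteny — this is a stated
blind spot of the approach, not an error. A table of externally computed
sequence-similarity hits may be supplied; a hit alone is sufficient
evidence ("either criterion"), and a lncRNA with both kinds of evidence is
annotated as such.

## Pair analysis

"Nearby mRNA" is operationalised as the single nearest coding gene by
TSS-to-TSS distance within 500 kb, strand-agnostic, so divergent promoter
pairs are captured; a flag switches to all-genes-in-window. Log2 fold
changes use the class detectability cutoff as pseudocount
(`log2((post + c)/(pre + c))`, c = 0.1 lncRNA / 1.0 mRNA), after excluding
genes at or below the cutoff in **both** samples. Regulation calls are
boundary-inclusive at 1.5-fold on the log2 scale.

Pairs regulated in both members and both datasets are classified:
*coherent-up* (all four directions up), *coherent-down* (all four down),
*anti* (lncRNA opposite to mRNA within each dataset, lncRNA direction
consistent across datasets), else *incoherent* — so a pair concordant
within each dataset but flipped between datasets is incoherent.

The cross-species sign test takes the pairs with |R| ≥ 0.3 in both species
(absolute value, because the scatter of correlations spans negative values;
a signed mode exists behind a flag) and asks whether the number of
sign-agreeing pairs is compatible with a fair coin: the exact two-sided
binomial p-value by the minimum-likelihood convention, i.e. the sum of all
outcome probabilities no larger than that of the observed count. For 54
agreeing pairs of 79 this gives p = 0.001466. (The same data are sometimes
quoted with a doubled one-sided or mid-p value near 0.00095; this package
implements the exact-test convention and makes no attempt to reproduce
other conventions.)

The hypergeometric overlap test is the exact upper tail
P(X ≥ |A∩B|), X ~ Hypergeom(N = |universe|, K = |A|, n = |B|). The
rank-sum comparison enumerates all group assignments exactly for combined
n ≤ 12 (half-count convention for ties) and otherwise uses the
tie-corrected normal approximation.

## Guilt-by-association

Partners are coding genes with signed Pearson R ≥ 0.7 against the query
across the sample panel. Enrichment replaces external engines with an
auditable hypergeometric over-representation analysis over GMT sets:
the universe defaults to the coding genes in the panel, sets overlapping
the selection by fewer than 3 genes are dropped before multiple testing,
and Benjamini–Hochberg q-values are attached (raw-p mode by flag).

## The synthetic-data generator

The generator's job is planted, recoverable truth — not biological realism.

**Genomes.** Each lncRNA sits in its own *cassette*: 2–4 protein-coding
genes per side, all within the 500 kb window of the lncRNA, with
consecutive cassettes separated by more than the window. A planted
perturbation therefore changes exactly one lncRNA's neighbourhood. Species
B mirrors species A's cassette order through a one-to-one ortholog map;
per-lncRNA roles are *conserved* (identical flanking order in B),
*shuffled* (the two nearest flanking genes swapped in B — order broken with
shared genes still ≥ 2, so the failure is a genuine order violation),
*absent* (no B counterpart), or *desert* (placed on a chromosome without
coding genes; unresolvable by synteny, emulating the ~half of real lncRNAs
the window criterion cannot address). All genes on a chromosome share its
strand. Catalog-stage decoys failing exactly one filter each (low coverage,
short, single-exon, high coding score, sense overlap) are planted alongside
the true lncRNAs; per-tissue assemblies jitter 3′-terminal exon ends by up
to 50 bp to exercise intron-chain matching.

**Expression panel.** Per-tissue log2 FPKM baselines are normal with mean 0
(lncRNA) and 3 (mRNA), SD 1.5, matching the observation that lncRNAs are
the lower-expressed class. Planted specific genes allocate a 0.6 share to
one tissue; broad genes draw a near-uniform Dirichlet allocation rejected
until its maximum sits strictly below the 0.1 call threshold, so zero-noise
classification is exact (this cap requires a panel of ≥ 12 tissues; the
default is 22). Conserved lncRNAs are always broad — they are the
ubiquitously expressed class — which produces the higher median pairwise
tissue correlation for conserved vs non-conserved lncRNAs that the
specificity module is asked to detect. The planted specific fraction
applies to lncRNAs (default 0.5) and at 0.4× that rate to mRNAs, giving the
expected class contrast in maximal fractions. Multiplicative log-normal
noise (`noise_sd_log2`, default 0.4 — a typical bulk-RNA-seq
replicate-level spread) is applied per cell.

**Time courses and contrasts.** The default planted coherence classes are
43 coherent-up, 22 coherent-down, 8 anti and 20 incoherent pairs (93
regulated pairs in total); remaining pairs drift near fold change 1
(log2 SD 0.15). Planted |log2 FC| is drawn uniformly from
[log2(1.5) + 0.915, log2(1.5) + 2.415] (≈ 2.8–8-fold, the range typical of
strongly regulated adipogenic genes), far enough from the 1.5-fold call
boundary that default-noise misclassification stays in the low percent.
The thermoneutral/cold contrast plants per-pair direction templates either
from explicit cell counts or from a positive fraction (default 0.842) with
a downregulation bias (0.6). Correlation panels give each planted pair a
shared latent sample effect, `member = sign·(ρ·z + σ·ε)` on the log2 scale
(ρ = 0.8 default): with noise off the pair correlation is exactly ±1, so
planted signs and the co-expression partner module are recovered exactly.

**What is not emulated** — and hence what passing tests do *not* show about
real data: no reads or alignment noise, no assembly fragmentation or
mis-assembly, no isoform complexity beyond 1–2 isoforms, no sequence
evolution (FASTA output is random bases, sufficient only for ORF-scan
tests), no batch or library-size effects, no correlated noise across genes.
Recovery metrics on this generator measure the correctness of the
*analysis logic* under controlled noise, not the robustness of the whole
upstream pipeline.

**Determinism.** One seed drives everything; each stage draws from a
deterministically derived `SeedSequence` sub-stream, so identical configs
give bit-identical outputs, and the end-to-end run writes a sha256 manifest
that is stable across reruns.

## Problem sizes and numerical conventions

Default runs use 120 lncRNAs and 760 coding genes on 4 chromosomes —
enough for 93+ pairs and a 12-lncRNA conserved set while keeping a full
end-to-end run around a second. The catalog-scale cold-exposure
reproduction uses 840 lncRNAs / 6000 coding genes (711 pairs). Ensemble
metrics average 10 seeds.

Floating-point conventions: fold-change and regulation comparisons carry a
1e-12 guard so that exactly-boundary values (e.g. log2(1.5)) compare
inclusively; fraction sums are asserted at 1e-9; expression matrices
round-trip bit-identically through TSV (full-precision write, round-trip
parse). Binomial two-sided summation uses a 1e-9 relative guard when
comparing outcome probabilities, matching the standard exact-test
convention.

## Known limitations

- Coverage is per-transcript assembler coverage, not per-base depth; the
  two can disagree for long transcripts with uneven coverage.
- Synteny window monotonicity (larger windows never losing a match) holds
  on the cassette-structured generator but is not a theorem under the
  restricted-to-shared order comparison: newly admitted genes can in
  principle introduce order violations; this is asserted empirically, not
  proved.
- The exact rank-sum enumeration is limited to combined n ≤ 12 (cost grows
  combinatorially); above that the tie-corrected asymptotic is used.
- Novelty requires exonic overlap; a locus-level (intron-inclusive)
  overlap would call more transcripts annotated.
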