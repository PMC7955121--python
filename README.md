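# persister-rx

Targeted cancer therapies rarely kill every tumor cell: a small
subpopulation of **drug-tolerant persister (DTP) cells** survives treatment
in a distinct transcriptional state and can later resume growth and seed
resistance. A practical route to attacking these cells is transcriptional
drug repurposing: identify the marker genes of each drug-tolerant state
from single-cell RNA-seq, then search a perturbation-response database for
small molecules whose consensus transcriptional signature *down-regulates*
those markers — candidates for combination therapy with the primary drug.

`persister-rx` implements that analysis end-to-end as a tested Python
library and command-line pipeline:

1. **Marker detection** — cell QC on detected-gene counts, LogNormalize
   (`ln(1 + c_gj / Σ_g c_gj · 10⁴)`), and one-vs-rest Wilcoxon rank-sum
   tests per cluster with Bonferroni-corrected *p* < 0.05,
   |log₂FC| ≥ 0.1 and percent-expressed ≥ 1% thresholds. Also: Seurat-style
   per-cell module scores, dot-plot statistics (avg.exp, pct.exp,
   avg.exp.scaled) and silhouette-width cluster QC.
2. **Drug signatures (PRL)** — per cell line, the weighted-average fold
   change over all conditions of a drug ranks the genes; the per-cell-line
   rankings are merged by a hierarchical majority-voting scheme (closest
   pair by Spearman footrule, merged by Borda mean rank) into one
   **Prototype Ranked List** per drug.
3. **Drug ranking by preranked GSEA** — the weighted Kolmogorov–Smirnov-like
   running-sum enrichment score ES of a marker set in each PRL, normalized
   (NES) and assessed against a gene-set-permutation null; drugs are
   reported sorted by NES ascending, so the strongest down-regulators of
   the marker set lead, with tail-ratio FDR and −log₁₀(Q) significance.
4. **Patient stratification (SLEA)** — per-sample z-score comparing the
   mean expression of the marker set to means of random same-size gene
   sets; samples with z > 1.96 and BH-FDR q < 0.05 form the marker-high
   group, compared against the rest by log-rank test and univariate Cox
   proportional hazards (Kaplan–Meier curves included).
5. **Overlap enrichment** — right-tail binomial test of marker lists
   against annotation collections (GMT) over a detected-genes background,
   BH-corrected, with the report-style heatmap filter (set size, minimum
   overlap, significance, contrast-condition exclusion).

A first-class **synthetic-data module** generates seeded inputs with the
statistical structure each stage assumes — negative-binomial single-cell
counts with planted cluster markers, a drug × cell-line fold-change
database with a planted down-regulator, and a cohort whose survival hazard
depends on a marker-enrichment signature — so the whole pipeline is
testable without any external download.

## Worked example

Run the all-simulated demo (2,000 genes; 5 clusters × 300 cells with fifty
4-fold markers planted in cluster 2; 50 drugs × 3 cell lines × 3
conditions with drug `D000` planted to down-shift the marker genes by 2;
a 126-sample cohort with a true hazard ratio of 2 for marker-high
samples):

```bash
persister-rx run --seed 7 --outdir out/
```

`out/ranking.tsv` starts:

```
drug    es       nes      p      fdr_q  neglog10_q
D000    -0.983   -4.270   0.004  0.000  4.398
D029    -0.351   -1.564   0.011  0.161  0.793
D031    -0.350   -1.564   0.023  0.161  0.793
```

The planted down-regulator `D000` attains the most negative NES by a wide
margin (−4.27 against −1.56 for the best null drug) with permutation
p = 0.004 — the demo recovers the planted drug at rank 1. `out/markers.tsv`
holds the 75 detected marker records (all fifty planted genes among them),
and `out/stats.json` summarizes the survival comparison of SLEA-high
versus rest:

```json
{"cox_hr": 1.66, "cox_ci95": [1.09, 2.52], "logrank_chi2": 5.69,
 "logrank_p": 0.017, "n_high": 51, "n_rest": 75}
```

i.e. the 51 marker-enriched samples have significantly shorter survival
(log-rank p = 0.017), as planted. Re-running the same command reproduces
every result table byte-for-byte; `out/manifest.json` records each stage's
parameters, derived seed, outputs and row counts.

Each stage is also available separately (`simulate`, `markers`, `score`,
`prl`, `query`, `slea`, `enrich`); see `persister-rx <cmd> --help`.

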