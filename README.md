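# ntchrom

Chromatin-state analysis of histone-mark reprogramming in cloned
(nuclear-transfer) embryos, rebuilt as a tested Python pipeline and
exercised end to end on synthetic data with planted ground truth.

Somatic-cell nuclear transfer (SCNT) embryos reprogram H3K4me3 and H3K27me3
poorly: at the 2-cell stage they accumulate aberrantly **broad promoter
H3K4me3 domains** and **excess promoter H3K27me3**, silencing zygotic genome
activation (ZGA) genes in a bivalent state, while gene-body **H3K36me3** —
normally mutually exclusive with both promoter marks — is depleted;
overexpressing the H3K36me3 methyltransferase SETD2 restores it and evicts
the aberrant promoter marks. This package implements the quantitative
machinery behind that analysis for anyone who wants to run, test, or adapt
it:

* **Four-state bin calling** — per 200-bp bin, a mark is called when
  input-normalized fold enrichment `FE = ((chip+pc)/N_chip)/((input+pc)/N_input)`
  exceeds 4 (H3K4me3) or 2 (H3K27me3/H3K36me3); bins are then
  K4only / K27only / Bivalent / Unmarked.
* **H3K4me3 breadth taxonomy** — widest promoter-overlapping domain, classed
  broad (> 5 kb) / medium (1–5 kb] / narrow (0.2–1 kb] / control (≤ 0.2 kb),
  with stage-to-stage flow matrices.
* **Gene-level states** — promoter (TSS ± 2 kb) overlap > 200 bp with the
  relevant segments; 0/1 gene × stage matrices; bin-level state-transition
  counts; gain/loss and condition-specific marking fractions.
* **Expression × epigenome categories** — a median-of-ratios + Welch + BH
  differential-expression stand-in feeding the ob/us H3K4me3 and ue/od
  H3K27me3 gene categories (|log2FC| > 2, P.adj < 0.01, plus the matching
  epigenome delta).
* **Mutually-exclusive index** — `m_s = B_r/B_v` with
  `B_r = n_A·n_B/n_total` and `B_v = n_bi`, scoring how strongly a promoter
  mark's domains avoid H3K36me3 domains (m_s > 1 ⇒ exclusion), with a
  width-preserving shuffled null.
* **A synthetic-data generator** that plants all of the above — NF/NT/rescue
  conditions, four stages, planted categories and fold changes — so every
  step is scored against known truth.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

The numbered scripts under `analysis/` run the study on the default
synthetic genome (2 × 5 Mb, 800 genes, seed 0) and write tables under
`results/`. For instance:

```
$ python analysis/05_expression_integration.py
category counts: {'none': 644, 'obH3K4me3': 40, 'odH3K27me3': 40, 'usH3K4me3': 39, 'ueH3K27me3': 37}
recovery vs planted truth: sensitivity 0.975, FDR 0.000 (156/160 planted genes recovered)
gene-body H3K36me3 coverage: NF 0.464, NT 0.113, Setd2OE 0.464
H3K36me3 vs expression Pearson r (NF): 0.934
k-means cluster sizes (gene-body H3K36me3 across conditions): {0: 353, 1: 179, 2: 268}
```

Of the 160 planted category genes (40 per category), 156 are recovered with
no false calls; NT gene bodies keep only 11% H3K36me3 coverage versus 46% in
NF, and the rescue condition restores the NF level exactly — the planted
phenotype, read back by the pipeline. Similarly:

```
$ python analysis/06_exclusivity.py
H3K4me3 vs H3K36me3: m_s = inf (shuffled median 2.69; planted > shuffled in 100.0% of 200 trials)
H3K27me3 vs H3K36me3: m_s = inf (shuffled median 6.08; planted > shuffled in 100.0% of 200 trials)
```

The planted architecture has *zero* co-marked domains (m_s = ∞, perfect
exclusivity); shuffling the H3K36me3 domains while preserving their widths
collapses the index toward its random level in every one of 200 trials.

The same steps are available as a CLI for file-based inputs
(`ntchrom simulate | enrich | states | domains | breadth | gene-state |
integrate | cluster | exclusivity | run-all`); `ntchrom run-all --seed 0
--outdir out/` reproduces the whole workflow and writes `summary.json` with
every threshold echoed.

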