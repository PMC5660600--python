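# cnvatten

Post-transcriptional attenuation of copy-number variation in tumour
multi-omics data.

Somatic copy-number variants (CNVs) usually propagate to mRNA, but a
substantial fraction of proteins — protein-complex subunits above all —
are buffered post-transcriptionally: their abundance tracks the complex,
not their own gene dosage. `cnvatten` implements the full analysis that
quantifies this effect from matched CNV / transcriptome / proteome
matrices of a tumour cohort, together with a synthetic-cohort generator
with known ground truth so every stage can be validated end to end.

It is a library for people working with proteogenomic cohorts
(CPTAC/TCGA-style gene-level matrices) who want attenuation statistics,
complex co-regulation analysis and rate-limiting subunit inference
without re-deriving the statistics.

## What it computes

- **Attenuation score** per gene (or per sample):
  `score = r(CNV, mRNA) − r(CNV, protein)` with pairwise-complete Pearson
  correlations. Positive scores mean the dosage signal reaching the
  transcript is lost at the protein level. A two-component Gaussian
  mixture separates attenuated entities from the background; a stringent
  call additionally requires |score| > 0.3.
- **Gene-set enrichment** of the (KDE-mode-centered) scores: weighted
  Kolmogorov–Smirnov running-sum ES with a random-membership permutation
  null and Benjamini–Hochberg FDR.
- **Co-regulation**: all-pairs Pearson correlation at protein and
  transcript level, and AROC of correlation as a classifier of complex /
  functional / signaling / metabolic interaction pairs, with randomised
  negative sets.
- **Rate-limiting subunits** by two-stage residual regression: stage one
  `P_y = β₁·T_y + ψ` gives residuals `P_y′ = P_y − β₁·T_y`; stage two
  `P_y′ = β₂·X_x + ψ` (X = partner's CNV or transcript) with an F-test of
  β₂ and BH FDR across all directed complex co-membership pairs.
- **Attenuation-potential signature**: per-sample attenuation potential,
  its per-gene expression correlates, signature scoring of new samples,
  a repeated 70/30 logistic benchmark, and per-drug response regressions.
- **Preprocessing**: CPM filtering of counts (mean CPM ≤ 1 excluded,
  log2(CPM+0.5)), Jaccard proteome coverage, linear removal of
  age/gender/tumour-type/technology confounders, ≥50% presence filtering,
  KDE-mode centering.

## Worked example

```python
from cnvatten import SimulationConfig, attenuation_table, simulate_dataset

dataset = simulate_dataset(SimulationConfig(seed=1))   # 2,000 genes x 282 samples
table, report = attenuation_table(
    dataset.cnv, dataset.mrna, dataset.protein, min_obs=15, seed=0
)
```

Running `python examples/gene_attenuation.py` (the same computation plus
a ground-truth comparison) prints:

```
genes scored: 2000
component means (background, attenuated): [0.099, 0.647]
attenuated calls: 184 (9.2%)
stringent calls (|score| > 0.3): 184
sensitivity vs ground truth: 1.000
specificity vs ground truth: 0.999
```

The mixture model finds a background component at score ≈ 0.1 (dosage
propagates to protein) and an attenuated component at ≈ 0.65, and its
calls recover essentially every gene the generator simulated with a
buffering factor γ < 1. The other `examples/*.py` scripts walk through
co-regulation (protein-level complex-pair AROC ≈ 0.87 vs ≈ 0.51 at the
transcript level), recovery of an implanted rate-limiting edge, set
enrichment, and the sample-level signature with drug associations.

A thin CLI mirrors the library (`cnvatten simulate|preprocess|attenuation|
enrich|coreg|regulators|signature|run`); `cnvatten run --simulate --seed 7
--out run/` executes the whole pipeline and writes a manifest.

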