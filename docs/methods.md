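# Methods

## The problem and the statistics

A gene's copy-number state (GISTIC-like integers −2…2) generally shifts
its mRNA level, but protein abundance can be decoupled from the gene's
own dosage when the protein's level is set post-transcriptionally — most
prominently for protein-complex subunits, which are degraded when
produced beyond the complex's stoichiometry. The package quantifies this
with correlation-based statistics that need only matched gene-level
matrices (genes × samples) at three molecular levels.

**Attenuation score.** For each gene, the Pearson correlation of CNV
with mRNA and of CNV with protein is computed over pairwise-complete
samples; the score is their difference `r(CNV,T) − r(CNV,P)`. Because
transcription sits between dosage and protein, `r(CNV,T)` is effectively
an upper bound for `r(CNV,P)`; the score therefore measures the dosage
signal lost post-transcriptionally, and lives in [−2, 2] (in practice
[0, ~1]). A two-component Gaussian mixture is fitted to the scores; the
component with the larger mean is called *attenuated*. The per-sample
version (*attenuation potential*) applies the identical statistic across
genes within one sample.

**Enrichment.** Scores are centered at the mode of a Gaussian KDE
(Silverman bandwidth) — the bulk of the distribution, not its mean, maps
to zero, which matters because the attenuated tail is one-sided. The
ranked list is tested with a weighted Kolmogorov–Smirnov running sum
(hit increments ∝ |score|, weight exponent 1; uniform miss decrements).
Significance comes from random gene-set-membership permutations (the
ranking has no phenotype labels to permute), two-sided on |ES| with +1
smoothing, and BH FDR across the collection.

**Co-regulation.** All C(n,2) gene pairs are correlated at each level
using a masked-matrix formulation of pairwise-complete Pearson (a few
genes × genes matrix products instead of a pair loop). Interaction
prediction is scored as the AROC of correlation against known positive
pairs; because positives are vastly outnumbered, each of (default) 5
draws samples an equal-sized negative set without replacement from
non-positive pairs, and mean ± sd over draws is reported. Correlation
itself (not |r|) is the ranking score: negative co-regulation ranks low.

**Rate-limiting subunits.** For a directed pair x→y within a complex,
stage one regresses y's protein on y's transcript (OLS with intercept)
and keeps the residual P′ᵧ — the post-transcriptional part of y's
abundance. Stage two regresses P′ᵧ on x's CNV (treated as numeric) or
x's transcript, with the F-test of the slope against the intercept-only
model (for one predictor F = t²) and BH FDR within each predictor-level
family separately. Positive significant slopes nominate x as
rate-limiting for y; negative slopes flag mutual-exclusivity
(paralog-substitution) pairs. Predicted slopes can be compared to
knockdown panels by Spearman correlation over shared (x, y) pairs.

**Signature.** The per-sample potential is correlated with every gene's
expression to give a signature vector; a new sample is scored by the
Pearson correlation of its expression profile with that vector across
shared genes (≥ 50 required). The signature's discriminative power is
benchmarked with repeated stratified 70/30 splits: ANOVA-F feature
selection with BH FDR (< 5%) on the training split, then an L2 logistic
model with regularisation strength chosen from {0.01, 0.1, 1, 10} by
5-fold stratified CV, evaluated by held-out AROC. Drug response (AUC,
higher = more resistant) is regressed per compound on predicted
potential with BH FDR across compounds; a positive slope reads as
"attenuation ⇒ resistance".

## Preprocessing

- Counts: genes with mean CPM ≤ 1 across samples are removed; survivors
  are returned as log2(CPM + 0.5). TMM/voom-style normalisation is out
  of scope here — the downstream statistics are correlations and are
  insensitive to per-sample scale factors — so log-CPM stands in.
- Confounders (age continuous; gender, tumour type, measurement
  technology categorical) are removed gene-wise by OLS on a one-hot
  (drop-first) design with intercept. The corrected value is residual +
  intercept, so gene-level means survive and abundances stay on an
  interpretable scale. Missing entries are excluded from each fit and
  stay missing; genes with fewer complete observations than design
  columns + 2 are left uncorrected with a logged warning, and
  single-level categoricals are dropped from the design.
- Proteins must be measured in ≥ 50% of samples (presence filter).
- Matrices are centered gene-wise at the KDE mode (see above); the
  operation is idempotent and maps constant genes to zero.
- Proteome coverage per sample is the Jaccard index between expressed
  transcripts and measured proteins.

## Synthetic cohorts

The generator produces the statistical structure the analysis assumes,
with ground truth. Per gene i and sample j:

    CNV_ij ~ categorical{−2…2},  default probs (.05, .2, .5, .2, .05)
    T_ij   = μ_i + a_i·CNV_ij + covariate effects + N(0, σ_T²)
    P_ij   = ν_i + μ_i + γ_ij·(T_ij − μ_i) + (1 − γ_ij)·C_kj
             + technology effect + N(0, σ_P²)

with a_i ~ U(0.5, 1.5), σ_T = σ_P = 0.5, and C_kj ~ N(0, 1) a latent
complex abundance shared by subunits of complex k and independent of
every CNV — so buffering strictly lowers r(CNV, P) without creating
spurious dosage associations. γ_i = 1 is pass-through (the formula then
reduces to P = ν + T + noise); attenuated subunits default to γ = 0.2.
A rate-limiting edge (x, y, δ) adds δ·(CNV_x − mean CNV_x) to P_y.
Covariate effects are additive on mRNA (age, gender, tumour type) and on
protein (technology), with per-gene coefficients drawn at the configured
effect sds, so confounder regression has something real to remove.
Protein entries are masked MCAR at a configurable rate (default 10%).

Defaults mirror a pan-cancer proteogenomic cohort: 282 samples, 2,000
genes, 30 disjoint complexes of 4–10 subunits, one pass-through
(rate-limiting-candidate) subunit per complex and γ = 0.2 for the rest
— a γ gap of 0.8 between attenuated and pass-through genes. An optional
per-sample heterogeneity knob marks a fraction of samples as
high-potential by lowering their effective γ for attenuated genes (the
mechanism used to validate the per-sample classifier).

What the generator does **not** emulate: continuous dosage within a
GISTIC state, informative (abundance-dependent) missingness,
translation-vs-degradation mechanisms, chromosome-arm events, isobaric
ratio compression, or correlated complex memberships (complexes are
disjoint). Passing tests therefore demonstrate the statistics are
implemented correctly and are well calibrated under the assumed
structure — not that real cohorts satisfy that structure.

## Numerical choices

- Pairwise-complete Pearson is computed from masked sums after row
  centering; rows/pairs with < `min_obs` (default 15) complete pairs or
  zero variance yield NaN and are excluded from scoring.
- GMM: scikit-learn, 2 components, k-means initialisation, 10 restarts,
  tol 1e−6, fixed seed; labels from the posterior argmax with ties
  (posterior = 0.5) assigned to background; near-constant score vectors
  (sd < 1e−6) fall back to a single background cluster.
- KDE mode: Gaussian KDE with Silverman bandwidth evaluated on a
  512-point grid spanning the data ± 3 bandwidths.
- GSEA ES: the running-sum extreme is attained adjacent to hits, so only
  2m candidates are evaluated; magnitude ties resolve to the extreme
  reached first along the ranking. Sets with < 5 scored members are
  skipped. Ranking ties break by gene id for determinism.
- Empirical p-values use +1 smoothing and can never be 0; BH is
  statsmodels' `fdr_bh`.
- Second-stage regressions use only samples where both residual and
  predictor are present (no imputation); residuals are not
  re-standardised, so slopes are in protein-abundance units.
- All randomised procedures (GMM restarts, permutations, negative-set
  draws, benchmark splits, simulation) take explicit integer seeds; a
  pipeline rerun with the same config is byte-identical.

## Validation problem sizes

The bundled validation experiments (tests and `scripts/acceptance.py`)
use: the full default cohort for attenuation recovery and co-regulation
ordering; 282-sample cohorts with 30–48 genes for the regulator
calibration (10 null seeds), power (100 seeds, edge size 0.5 × residual
sd, two-pass calibration of δ) and FDR control (50 seeds, 9 true edges
among 180 directed pairs); a 200 × 600 cohort with a planted 20%
high-buffer subgroup for the per-sample classifier; and 300-gene,
200-sample expression for the signature benchmark (100 splits). The
pair-count identity materialises both 6,434-gene correlation tables on a
thin 30-sample matrix, since the count depends only on the gene
universe. The pipeline's default GSEA permutation count is 200 (the
`gsea` function itself defaults to 1,000).

## Known limitations

- The GMM attenuated/background split assumes two score populations; a
  continuum of buffering strengths yields boundary-dependent counts
  (plain and stringent counts are both reported for this reason).
- AROC negatives are any non-positive pair for the set under
  evaluation; positives of *other* interaction sources are not excluded.
- The attenuation potential is sensitive to the cohort's CNV burden;
  correlating it with external burden/purity/ploidy annotations is left
  to the caller via the generic correlation utilities.
- With heavily non-Gaussian predicted-potential distributions the
  per-drug OLS p-values are only asymptotically calibrated.
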