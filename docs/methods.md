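# Methods

This note documents the statistical procedures implemented in `mima`, the
assumptions they make, the parameters that matter, and the choices taken
where the design was genuinely open.

## Data model

The unit of analysis is a small longitudinal cohort: `n_crew` subjects
(default 4) sampled at `n_timepoints` occasions (default 6), with pseudo-bulk
gene expression per annotated immune cell type (default 9 labels: an
aggregate PBMC profile plus CD4 T, CD8 T, other T, B, NK, CD14 monocyte,
CD16 monocyte, and dendritic cells) and microbial feature abundances per
(domain, rank) — bacteria or viruses at phylum/genus/species. Sample ids
follow `crew<k>_T<j>`; the subject id is the grouping factor for all mixed
models. Body sites are pooled into one matrix per (domain, rank) by default;
per-site matrices can be generated by keying `n_microbes_per_rank`
accordingly, and nothing downstream assumes pooling.

## Transforms

* **Pseudocount** — every abundance matrix is shifted by its smallest
  strictly positive entry before any log-scale operation. A literal minimum
  would be 0 for any matrix containing zeros and would leave the log
  undefined; the smallest-positive reading is the only self-consistent one.
* **Log / CLR** — natural log elementwise, or centered log-ratio per sample
  (column): `ln x_i − mean_j ln x_j`. The CLR axis is the compositional
  convention (within sample, across features). Output columns sum to zero to
  1e-9 and the transform is invariant to per-sample rescaling; both are
  asserted as tests. Log base only shifts both transforms by a constant
  factor and cannot change LASSO support or mixed-model p-values.
* **Expression scaling** — each gene is centered and scaled to unit *sample*
  SD (n−1 denominator; documented so arithmetic oracles match). Constant
  genes are excluded with a logged warning.

## Stage 1 — LASSO screen

One model per (gene, microbial matrix, transform): the gene's scaled
expression regressed on *all* features of the matrix, predictors
standardized inside the fit, intercept included. p ≫ n is the intended
regime; zero-variance features are dropped with a warning, nothing else is
pre-filtered. Any non-zero coefficient at the selected penalty is a
candidate association. Candidates are deliberately liberal: their false
positives are controlled by stage 2, so the penalty is chosen by 5-fold
cross-validation *minimizing* MSE (`cv_min`, the default). `cv_1se` (the
sparsest penalty within one SE of the minimum) and a fixed penalty are
available.

Solver numerics: the penalty path uses 30 log-spaced values down to 1e-2 ×
the critical penalty, coordinate-descent tolerance 1e-3, max 2000
iterations. Long default paths are an order of magnitude slower on
correlated log-abundance predictors without changing the selected support in
the regime tested. Folds are shuffled with a fixed seed; identical seeds
give identical candidate lists. With duplicated or collinear predictors the
support returned by the deterministic solver is kept as-is — determinism,
not uniqueness, is the contract.

## Stage 2 — mixed-model inference

Each candidate is refit as `gene ~ microbe + (1 | crew)` on the same
transform used in stage 1. The fit profiles the variance ratio
λ = σ²crew/σ²resid in one dimension (the profiling strategy lme4 uses for a
single random intercept): for fixed λ the fixed effects and the residual
variance have closed forms via per-group downweighting, leaving a bounded
scalar optimization over log λ. The slope and its SE are the GLS values at
the REML optimum.

The two-sided p-value is a Wald *t* with **Satterthwaite** denominator df:
df = 2·var(β̂)² / (gᵀ A g), where g is the gradient of var(β̂) with respect
to the two variance components and A the inverse expected REML information.
This matters: with 4 subjects, a plain z reference (and even a fixed
residual-df t) is severely anti-conservative in the far tail — precisely the
tail the Bonferroni rule probes — and most of all for predictors whose
variation is mostly *between* subjects, where the effective df collapses
toward the number of subjects minus two. The implementation reproduces
lmerTest (REML + Satterthwaite) estimates to four decimals on validation
cases spanning both within- and between-subject predictors.

Degenerate inputs: a constant microbe vector is an error; a single subject
or a boundary REML fit (zero subject variance, threshold 1e-8) falls back to
ordinary least squares — which the mixed model then equals — and is flagged
`method="ols"` in the output. p-values are clamped into (0, 1] at the
smallest positive float.

### Stringency levels and the Bonferroni scheme

Three nested tiers: non-zero LASSO coefficient; nominal p < 0.05;
"Bonferroni < α" meaning raw p < α / (n_microbes(domain, rank) ×
n_DEGs(cell type)), evaluated at α = 0.05 and 0.2. The family is the full
set of tests a (cell type, matrix) screen could have generated, not just the
candidates actually refit — the most conservative reading. Nesting
(bonf_005 ⊆ bonf_020 ⊆ nominal) is enforced by construction, since for very
small families 0.2/family can exceed 0.05.

Per-cell-type summaries count Bonferroni(0.05) hits with positive slope;
gene rankings sort by (# Bonferroni(0.2) hits, # nominal hits), drop genes
with no nominal hit, truncate to 10, and break ties on the gene id for
determinism.

### Randomization check

The null comparison re-runs the full two-stage pipeline on a randomized copy
of the cohort and reports hit counts and pair-identity overlap at each
stringency level. The default scheme permutes the sample labels of each
cell type's expression matrix (one permutation per cell type), which breaks
the gene–microbe pairing while preserving both marginals; an alternative
(`permute_genes`) shuffles each gene independently and additionally destroys
the subject structure of expression. With several randomizations the
randomized-side counts are averaged.

## Enrichment statistics

* **Fisher overlap** — one-sided (enrichment) exact test of |A∩B| in a
  stated universe; equals the hypergeometric upper tail; the odds ratio is
  the sample odds ratio of the 2×2 table. Two-sided available via flag.
* **ORA** — hypergeometric upper tail per annotation set, BH across sets.
* **BH adjustment** — standard step-up; verified against an independent
  implementation in the tests.
* **Preranked GSEA** — weighted KS running sum with weight exponent 1
  (|score|¹ hit increments; configurable). Null: random same-size gene sets
  from the ranking (gene-label permutation). p is one-sided on the sign of
  the observed ES with +1 smoothing, so it converges to the enumeration p as
  permutations grow; NES divides ES by the mean |ES| of same-signed
  permutation values, and sets with no same-signed permutation get an
  undefined NES and are excluded from the BH family with a warning. Sets
  with no ranked genes, or covering the whole ranking, are dropped with a
  warning. Ranking ties break on gene id. Three ranking metrics are
  provided (−log10(p)·sign(log2FC); log2FC·−log10(p); a passthrough `stat`
  mode); none is privileged.
* **Pathway score & cross-study comparison** — `−log10(padj)·sign(NES)` per
  pathway; two studies are compared by Pearson r and the OLS slope of B on A
  over the intersection of pathway ids (≥3 required; unmatched ids dropped
  and counted).
* **Compound enrichment** — per compound, hypergeometric upper tail of the
  overlap between its interacting genes and the DEG list, within the
  universal gene set (union of all compounds' gene sets). DEGs outside the
  universal set are dropped and counted. Bonferroni multiplies by the number
  of compounds tested *within one compound class* (drugs, food compounds and
  expression-perturbing compounds are separate families). Edge confidence
  scores are ignored by the statistic; gene ids are treated as an opaque
  namespace.

## Synthetic cohorts

The generator emulates the features the models rely on and nothing more:

* Microbial counts: zero-inflated log-normal (per-feature log-mean
  U(1, 5), log-SD 1.5, zero fraction `zero_inflation`, default 0.3), rounded
  to integers. This reproduces zero-heavy, heavy-tailed abundance tables
  without modeling read depth; there is no phylogenetic or temporal
  structure, and microbes carry no subject effect.
* Expression: per-gene baseline U(2, 8) (kept positive so ratio-based
  log2FC is well defined), Gaussian subject intercepts with SD `crew_sd`
  (default 0.5, drawn independently per gene), Gaussian noise with SD
  `noise_sd` (default 0.5).
* Planted effects: `n_planted` (gene, microbe) pairs in one designated cell
  type receive `effect_size` (default 1.0, in expression-SD per
  predictor-SD) × the z-scored log abundance of the microbe — i.e. effects
  live on the analysis scale, matching the models being tested. Planted
  slopes are positive so the positive-hit tally is informative.
* Companion generators plant enriched compounds (interaction sets
  over-sampling a DEG list) and concordant pathways (members drawn from the
  top of a supplied ranking).

What passing tests on these cohorts shows: calibration and power of the
procedure under its own assumptions. What they do not show: robustness to
temporal autocorrelation beyond the subject intercept, microbe–microbe
correlation, non-Gaussian expression noise, or compositional coupling
between planted and unplanted features — all present in real data.

## Experiment sizes and guarantees asserted in the test suite

* Closed-form statistics (Fisher, ORA, compound) match brute-force
  enumeration to 1e-10 on 200 random instances with universes ≤ 30.
* GSEA permutation p matches the exact distribution over all C(8,3)=56
  enrichment scores of an 8-gene ranking to ±0.015 at 20k permutations.
* Mixed-model type-I error over 2000 global-null replicates (4 subjects × 6
  timepoints, subject SD = noise SD = 0.5) lies in [0.03, 0.08].
* Across 100 global-null cohorts (200 genes × 50 microbes), the
  Bonferroni(0.05) rule yields zero discoveries in ≥95 (the log-transform
  arm carries these null experiments; the two transforms are separate
  families and behave alike).
* With effect 1.0, noise 0.5 and 8 subjects, ≥80% of 20 planted pairs are
  recovered at nominal significance and the planted cell type tops the
  positive-hit tally.
* On planted cohorts the real and randomized Bonferroni hit sets are
  disjoint in ≥95% of 50 runs.
* Two pipeline runs from one YAML config produce hash-identical outputs.

`scripts/acceptance.py` recomputes the same quantities at sizes that keep a
single run to ~2 minutes (20 null cohorts, 10 randomization runs); the test
suite carries the full-size versions.

## Known limitations

* Stage-2 p-values are computed on the same data that selected the
  candidates; the Bonferroni family (all possible tests, not just selected
  ones) is what keeps the procedure honest, and the family-wise control
  experiment verifies exactly this combination. Selection-adjusted
  ("post-selection") inference is out of scope.
* The Satterthwaite df uses the expected (Fisher) REML information;
  observed-information implementations can differ slightly on extreme
  between-subject predictors (checked case: df 11 vs 6 at p ≈ 0.11 vs 0.13).
* The mixed model has a single variance component; no temporal
  autocorrelation, no random slopes.
* The GSEA permutation null is gene-label permutation (the preranked
  convention), not phenotype permutation; multilevel/adaptive p-value
  schemes are not implemented, so very small p-values are floor-limited by
  the permutation count.
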