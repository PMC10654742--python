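# Methods

This note documents the models and procedures implemented in
`faimepath`, the defaults and why they were chosen, what the synthetic
cohort generator does and does not emulate, and the numerical
conventions that matter for reproducing results.

## Preprocessing

Counts are filtered and normalized in this order: (1) keep genes with
CPM strictly above 1 in at least 2 samples, where CPM is computed on
the **raw** library sizes; (2) median-of-ratios size factors on the
filtered matrix (per-gene reference = geometric mean across samples,
restricted to genes positive in every sample; sample factor = median
of count/reference); (3) log2(count/factor + 1). Filtering before
normalization keeps the filter a pure function of raw CPM; the
normalize-first order is available via `preprocess(filter_first=False)`.
The pseudo-count of 1 is the standard convention and is immaterial
downstream: pathway scoring is rank-based within each sample, so any
strictly increasing per-sample transform (including the choice between
log2 and normalized-count scales) leaves scores unchanged — the test
suite asserts this exactly.

Ties in the median over an even number of reference genes use the
midpoint convention. If no gene is positive in all samples the size
factors are undefined and the error message suggests pre-filtering; no
silent pseudo-reference is substituted.

## Single-sample pathway scoring

Within each sample, genes are ranked ascending (lowest expression →
rank 1; ties receive the average rank) and weighted by
w(r) = r·exp(−r/N), N the number of genes. A pathway's score is the
mean weight over its member genes minus the mean weight over all
non-member genes. Consequences used as invariants: scores are
antisymmetric under set complementation; a random gene set has
expected score 0; and scores are exactly invariant to monotone
per-sample transforms provided the tie structure is preserved.

The weighting function is isolated in `faime.rank_weights` so a
different rank-weight variant can be substituted in one place without
touching scoring or any downstream statistic; everything downstream is
conditional on this weighting.

Pathways mapping fewer than 5 genes of the expression universe are
dropped (the count is logged); set membership uses intersection
semantics — genes absent from the universe are ignored. Statistics
always run on raw scores. The per-pathway rescaling to [−1, 1]
(x′ = 2(x − min)/(max − min) − 1; constant rows map to 0) exists for
heat-map display and clustering only.

## Robust differential statistics

With per-tail proportion γ (default 0.2, the robust-statistics
convention that underlies the moderate-effect threshold below) and
k = ⌊γn⌋:

* winsorizing replaces the k smallest values by the (k+1)-th order
  statistic and the k largest by the (n−k)-th;
* the trimmed mean averages the central n − 2k values;
* dR = 0.642·(t̄_A − t̄_B)/s_W, where s_W pools the winsorized sums of
  squares over n_A + n_B − 2 df. The 0.642 constant rescales the
  20%-winsorized SD to the normal-theory SD so dR matches Cohen's d
  under normality; |dR| > 0.62897 marks a moderate effect and is kept
  as a named configuration constant;
* the test is Yuen's trimmed-mean Welch test (t = Δt̄/√(d_A + d_B),
  d_i = (n_i − 1)s²_{W,i}/(h_i(h_i − 1)), h_i = n_i − 2k_i,
  Welch–Satterthwaite df). A pooled-variance t on winsorized values is
  available via `method="pooled"`; Yuen is the default because it is
  the standard companion of dR. Degenerate cases: zero variance with
  equal trimmed means gives t = 0, p = 1; with unequal means a signed
  infinity and p = 0.

A pathway is called differential only under the dual rule:
Benjamini–Hochberg q < 0.05 (one BH pass across all retained pathways)
AND |dR| above the moderate threshold. The effect-size arm makes the
caller conservative under the global null: large cohorts can make
trivially small shifts significant by q alone, but not move |dR|.

The baseline patient-vs-control comparison is unadjusted (no
covariates), matching the study design this pipeline emulates.

## Clustering and association tests

Samples are clustered by Ward linkage on Euclidean distances over the
[−1, 1]-normalized scores (the representation the heat-map clusters are
read from; raw scores available behind a flag), and the tree is cut to
exactly k = 4 clusters by default — no automatic k selection. Clusters
are reported ordered by ascending patient fraction, exposing the
healthy-to-patient gradient. Covariate associations use Pearson
chi-square (no continuity correction; expected counts < 5 flagged) for
categorical covariates and one-way ANOVA for numeric ones; constant
covariates are reported as degenerate with p = 1.

For 2×2 clinical tables both the two-sided Fisher exact p and the
Pearson chi-square p (uncorrected) are computed and returned. On
sparse tables the two can disagree at the printed precision — for the
cohort's aspirin-by-outcome table (19/0 vs 9/5) the exact test gives
0.008 while Pearson gives ≈0.005 — so the exact value is the one
quoted and both are always reported.

Pathway root categories are obtained by following child→parent links
to a fixed point; pathways absent from the hierarchy are their own
roots.

## Cross-validated classification

Patients vs controls: L2-penalized logistic regression (C = 1,
features standardized within the training fold) under `runs` × 
stratified k-fold CV (default 20 × 10). The dual-criterion selection is
recomputed on each training fold only; if nothing passes, the top-1
pathway by |dR| is used (logged). Folds whose test set holds one class
are skipped and counted. The summary is the mean ± SD over all
held-out fold AUROCs. Stratification is used because the cohort's
class imbalance (≈2:1) makes unstratified folds of ~5 samples
frequently degenerate.

Progression: nested CV. Within each outer training fold, pathways are
ranked by the univariate Yuen p (ties by |dR|; Welch's t when a group
is too small to trim) and the top ⌈k·m⌉ kept for
k ∈ {1%, 5%, 10%, 20%}; an inner stratified CV (3-fold) tunes one
hyper-parameter per family — C for logistic, var_smoothing for
Gaussian naive Bayes, min_samples_leaf for a 100-tree random forest —
before the outer fold is scored.

Two protocol checks are built in. `selection_leakage_demo` contrasts
selecting features once on the full data (leaky) with in-fold
selection (honest) on label-independent data, quantifying the AUROC
inflation of the leaky protocol. `permutation_null_auroc` estimates
the chance level by averaging CV AUROC over many independent label
permutations: pathway scores are strongly cross-correlated (one
dominant latent factor), so a *single* permutation's CV AUROC is a
high-variance draw around 0.5 — means near 0.7 occur — and only the
average over permutations is a meaningful chance reference.

## ANCOVA change analysis

Per pathway, over patients only (controls have no follow-up sample):

Δᵢ = β₀ + β₁·[evolving]ᵢ + β₂·preᵢ + cluster indicators + εᵢ,

by OLS with classical standard errors (HC1 robust errors behind a
flag), Δ = follow-up − baseline score and pre the same pathway's
baseline score. Each pathway is adjusted on its own baseline only; a
multivariate baseline profile is deliberately not implemented. The
baseline clinical cluster enters as treatment-coded indicators;
clusters with a single patient cannot support an indicator and are
merged into the reference level with a warning. β₁ p-values are BH
adjusted across pathways; significance is q < 0.05. Degenerate fits
(zero residual variance) report p = 1. The per-group mean score before
and after is reported alongside so the direction of drift in evolving
versus stable patients is explicit, and root-category enrichment among
change-associated pathways is tested with an uncorrected chi-square on
the 2×2 of (root = target) × (significant), with both observed
proportions returned.

## Synthetic cohort generator

The generator emulates the study design: 16 healthy controls sampled
at baseline, 33 patients (19 stable, 14 evolving) sampled at baseline
and follow-up. Defaults: 4,000 genes, 200 pathways of 8–60 genes in a
single-level hierarchy over 18 root categories (all used), gene base
log2-means ~ Normal(5, 2), log-normal library factors (σ = 0.3 on the
log scale), negative-binomial counts with fixed dispersion 0.2 —
var = μ + 0.2μ², a typical bulk RNA-seq magnitude; a single
dispersion rather than a gene-wise trend is the simplest model that
exercises the pipeline's robustness features (dispersion 0 degenerates
to Poisson). All randomness flows from one seed through numpy's PCG64
generator, so identical specs give bit-identical cohorts; the pipeline
manifest records the seed.

Injected effects and ground truth:

* 20 *affected* pathways receive a log2 shift of 1.0 in all patient
  samples. Shift signs alternate across pathways and are balanced by
  gene count (greedy assignment, largest pathway first). The balance
  matters: rank-based single-sample scores are competitive within a
  sample, so a one-signed shift of ~17% of the transcriptome would
  displace the ranks of every unaffected gene and smear the group
  effect across all null pathways, making pathway-level truth
  unrecoverable by *any* caller; with sign balance the rank
  displacement cancels to first order.
* 15 *progression* pathways receive an additional ±1.0 log2 shift,
  alternating sign per pathway, only in the follow-up samples of
  evolving patients. Stable patients' follow-up samples are fresh
  draws from their baseline distribution — biological stability plus
  sampling noise.
* The genes of effect-carrying pathways are drawn from reserved,
  mutually disjoint blocks of the universe and excluded from null
  pathways, so no null pathway is partially affected and
  sensitivity/false-discovery proportions can be scored exactly
  against the truth record (which stores the pathway ids and signs).
  Null pathways may overlap one another freely, as real pathway
  collections do.

What the generator does **not** emulate: globin depletion and other
library-preparation artifacts, batch effects, gene–gene correlation
beyond shared pathway membership, gene-wise dispersion trends, and
partially overlapping effect pathways. Passing tests therefore show
that the statistics behave correctly under the stated model — honest
error control, power at the stated effect size, no selection leakage —
not that any particular biological effect size is detectable in real
blood transcriptomes.

## Problem sizes and numerical conventions

The test suite and acceptance script run the full-size design
(4,000 × 82, 200 pathways) wherever a quantity is pinned to the default
spec, and a scaled cohort (1,200 genes, 60 pathways) for module-level
checks; null-calibration and power summaries average over 20–50
simulated cohorts, and power/FDP estimates in the acceptance script
average over 5 cohorts because single-cohort false-discovery
proportions at ~20 calls are quantized in steps of ~0.05. Hand-checked
oracle values (winsorized examples, dR, Yuen t/df, BH arithmetic) are
asserted to 1e-9; scipy's trimmed two-sample t-test serves as an
independent cross-check of the Yuen implementation. BH adjustment is
delegated to statsmodels, clustering to scipy, exact/chi-square/ANOVA
tests to scipy.stats, and the classifiers to scikit-learn; the FAIME
weighting, the robust effect size, Yuen's test, and the median-of-ratios
normalization are implemented in this package.

## Known limitations

* Gene identity is the exact symbol string; no alias or identifier
  mapping is attempted (the "official symbol" test is a configurable
  regex, default: reject purely numeric tokens).
* One follow-up timepoint; no mixed-effects or time-to-event modelling.
* The baseline differential comparison is unadjusted; covariate
  adjustment exists only in the change analysis.
* The [−1, 1] view is a per-pathway range normalization and is not
  comparable across data sets.
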