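# Methods

`breathvoc` re-implements, as a tested pipeline over synthetic cohorts, a
discrimination analysis for exhaled-breath volatilomics: given GC/MS feature
intensities from breath samples of women classified as asthmatic with other
coexisting atopic diseases (A-AD), non-asthmatic with atopic diseases
(NA-AD) or non-asthmatic without atopic diseases (NA-NAD), build penalized
logistic models that separate the groups, quantify their significance by
permutation, and validate them on a held-out split.

## Data model

A dataset is a samples x features matrix of non-negative relative
intensities, feature annotations (retention time, quantifier m/z, optional
compound identity, contaminant class) and sample annotations (diagnostic
category, sampling season, residence zone, clinical covariates,
train/validation split). Every breath sample is paired with one ambient
(room-air) sample collected at the same visit. Missing intensities are
rejected at load — the upstream peak-detection workflow produces complete
matrices — unless zero-imputation is requested explicitly. The metadata
file's row order is canonical; all matrices align to it, which makes fold
assignment downstream deterministic. The train/validation split is
date-based with a half-open `[start, cutoff)` convention: samples dated
strictly before the cutoff train the models, the rest validate them.

## Hyper-filtering

Two screens produce the "hyper-filtered" feature set. First, features
annotated as gas-bag artifacts (N,N-dimethylacetamide, phenol), pump oils or
column siloxanes are dropped by their contaminant class — class-based
matching rather than name-string matching, so the screen cannot be defeated
by annotation spelling. Second, each remaining feature's non-normalized
intensities are compared between every breath sample and its paired room-air
sample with a one-sided Wilcoxon signed-rank test (ambient greater than
breath); features significant at alpha = 0.05 are removed as
environment-dominated. The direction is one-sided because the removal
criterion is specifically *higher* intensity in room air; compounds higher
in breath are the signal of interest. No multiplicity correction is applied
by default (a Benjamini–Hochberg option exists): the screen is a
conservative keep/drop gate, and correcting would keep more features, not
fewer. Zero differences are dropped and tied absolute differences receive
mid-ranks. The null distribution of the signed-rank statistic is computed
exactly — a dynamic program over the integerized mid-ranks equivalent to
enumerating all 2^n sign assignments — whenever at most 25 non-zero
differences remain, and by a normal approximation with continuity and tie
corrections otherwise.

## ASCA

ANOVA-simultaneous component analysis partitions the column-centered breath
matrix into one effect matrix per design factor plus a residual E. Factors
are the sampling season and the residence zone, as main effects only and in
that order; each factor's effect row is the per-feature mean of its level,
taken on the running remainder, so the identity `centered X = season effect
+ zone effect + E` holds exactly even for unbalanced designs (and reduces to
the classical orthogonal partition, with additive sums of squares, when the
design is balanced). Effect matrices are scored by simultaneous component
analysis (SVD); a permutation test on a factor's sum of squares is provided
as a diagnostic. Downstream models are fit on E.

Choices worth recording:

* **Training-only fitting.** ASCA level means are estimated on training
  samples only; validation samples are corrected by subtracting the stored
  training means (`residualize`), with a grand-mean-only fallback for levels
  unseen at fit time. This prevents validation information from leaking into
  the correction.
* **log10 transform.** The pipeline log10-transforms intensities before
  centering (the `asca` module itself applies no transform; the flag lives
  at the pipeline level, default on). GC/MS relative intensities are
  multiplicative — batch effects scale peaks rather than shift them — so
  additive factor effects are a better model on the log scale.
* No unit-variance scaling of features before decomposition.

## Penalized logistic discrimination

Models minimize `-(1/n) loglik + lambda * ||beta||_1` with an unpenalized
intercept. Variables are standardized to population unit variance before
fitting (binary covariates included, so the penalty treats all variables
uniformly); coefficients are reported on both scales and odds ratios refer
to one unit of the original variable. The solver is cyclic coordinate
descent with soft-thresholding on an iteratively reweighted quadratic
approximation, warm-started along a decreasing penalty path from
`lambda_max = max_j |x_j^T (y - ybar)| / n` down three decades, with an
active-set strategy between full sweeps and an objective-based step-halving
safeguard. Convergence is declared when the KKT stationarity residual of the
true objective falls below `tol` (default 1e-7 for single fits, 1e-6 inside
cross-validation loops); non-convergence raises rather than returning a
silently bad fit. At `lambda >= lambda_max` the solution is exactly the
intercept-only model; at `lambda = 0` it matches the unpenalized maximum
likelihood estimate (checked against an independent generic optimizer in the
tests).

The penalty is chosen by stratified five-fold cross-validation: the grid
minimizer of the mean held-out binomial deviance (an AUC criterion is
available), ties resolved toward the sparser model. No one-standard-error
rule by default. Fold assignment shuffles within class and deals
round-robin, so folds are stratified and deterministic given the seed.

## Performance estimation

Two-pronged, mirroring the study design:

1. **Cross-validated AUC.** Stratified five-fold CV on the training split;
   each fold's model is rebuilt from scratch with penalty selection nested
   inside the fold's own training portion, and scored by AUC on the held-out
   fold. AUC_CV is the arithmetic mean of the five fold AUCs. AUC itself is
   the tie-corrected concordance probability (identical to the trapezoidal
   ROC area). Significance comes from a permutation test: class labels are
   permuted, the statistic recomputed, and the p-value is the add-one
   estimator `(1 + #{null >= observed}) / (1 + B)` — strictly positive, with
   minimum `1/(B+1)`.
2. **External validation.** The final model (fitted on all training samples
   at the cross-validated penalty) is applied to the validation split,
   giving AUC_VS and a confusion table at a prevalence-based cutoff: a
   predicted probability at least the training case prevalence classifies as
   case (ties to case). Sensitivity and specificity are reported as half-up
   integer percentages.

The permutation test has two modes. The default rebuilds the entire model —
penalty re-optimization included — for every permutation; anything less
biases p downward because the observed statistic would enjoy a tuning
advantage the nulls lack. The fast mode freezes the penalty at the value
cross-validated on the observed labels and evaluates the observed statistic
and every permutation under that same frozen-penalty protocol; it is
labelled approximate because the frozen penalty carries information from the
observed labels, but an empirical check in the acceptance suite (200 null
replicates, B = 99) shows its type-I rate at nominal 0.05 stays within
[0.02, 0.08]. Benchmark-scale runs use the fast mode; single-model analyses
can afford the full rebuild.

## Cohort statistics

Percentages in the characteristics tables are `round_half_up(100 * count /
n)`. Continuous group comparisons are gated on normality: only when every
group passes both the Shapiro–Wilk and the Lilliefors test at the 0.05 gate
does the parametric branch run (t-test / one-way ANOVA); otherwise
Mann–Whitney U / Kruskal–Wallis. The AND-over-both-tests,
AND-over-all-groups rule is the conservative reading of "according to the
data distribution"; the gate decisions are recorded in the result.
Categorical association uses Fisher's exact test — two-sided by the
point-probability rule, stated explicitly because two-sided Fisher has
competing definitions — for 2x2 tables with any expected cell below 5, and
the chi-square test (continuity-corrected for 2x2) otherwise.

One fixture note: of the 92 printed count/percent cells in the two cohort
characteristics tables, 91 are reproduced exactly by half-up rounding; one
cell (paracetamol use among training-set non-asthmatics, printed "107
(56%)") is internally inconsistent — 107/186 is 57.5% — and is flagged as
such in the fixture rather than silently adjusted.

## Synthetic cohort generator

The generator emulates the features of the real data the analysis depends
on. Log10 intensities are `baseline(feature) + class_effect * [case &
discriminant] + season(feature, season) + zone(feature, zone) + N(0,
noise_sd)`; intensities are `10^log10`, hence lognormal and strictly
positive. Defaults: 200 features with baselines N(4, 0.8); three
discriminant features; noise sd 0.3 log10 units (about a factor-2
coefficient of variation, typical of breath GC/MS relative intensities);
season and zone effect sds 0.2 and 0.1 (batch effects comparable to but
smaller than the noise); case/control sizes 25 vs 186 and an NA-AD:NA-NAD
control split of 72:114, mirroring the training cohort; validation fraction
125/336 with dates consistent with the split cutoff and seasons derived from
the dates. Each breath sample has one ambient partner carrying
`ambient_fraction = 0.3` of the breath baseline, the same visit's
season/zone effects and fresh noise; five planted ambient-dominant features
are 10x that level, and four contaminant features are flagged in the
metadata. Binary covariates are drawn per category at rates patterned on the
cohort tables (e.g., parental asthma 24% in cases vs 4–8% in controls);
white-blood-cell counts are truncated Gaussians with an elevated eosinophil
mean in cases. Effect sizes: the benchmark profiles plant log2 shifts of 0
(null), 1 (moderate) and 2 (strong) on the discriminant features, with
fixed, documented seeds.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: chromatographic peak-shape artifacts, retention-time
drift and deconvolution errors; correlated feature blocks from shared parent
compounds; heavy-tailed or zero-inflated intensity distributions;
covariate–VOC dependence beyond the class labels; and any relationship
between the zone labels and actual exposure. Recovery rates on the benchmark
are an upper bound on what identically sized real cohorts would give.

## Numerical choices and degenerate inputs

Probabilities are clipped at |linear predictor| = 35 before the logistic
link to avoid overflow; the held-out deviance uses a 1e-12 floor. IRLS
weights are floored at 1e-5. Zero-variance variables are dropped before
penalized fitting, with a warning and a record. A factor level with no
samples is skipped; a constant factor yields a zero effect matrix with a
warning; an all-zero matrix passed to SCA returns zero scores and zero
explained fractions. All-zero paired differences give p = 1 with a warning.
Ties at the classification cutoff go to the case class.

## Problem sizes in the acceptance suite

Simulation-based acceptance checks run at sizes chosen for a single CPU:
the permutation-calibration check runs the null condition at 10 cases vs 40
controls with 30 features (the calibration property of a permutation test
does not depend on problem size), B = 99 and 200 replicates; the
planted-signal recovery check runs the strong profile at its full 25 vs 186
size for 20 fixed benchmark seeds with B = 99 and the fast permutation mode;
the ambient-screen operating characteristics use 50 seeds at 50 pairs and 60
features. The analysis drivers under `analysis/` run the full sixteen-model
catalog at the study-scale benchmark with B = 199.

## Known limitations

* The sixteen-model catalog encodes the study's variable-block groupings;
  where the exact membership of a block was ambiguous the catalog offers the
  full block (e.g., all six WBC counts) and lets the penalty select.
* The paper's own headline AUCs were computed on non-public cohort
  measurements and are not reproducible here; the pipeline's numbers come
  from the synthetic benchmark.
* The fast permutation mode is approximate (see above); studies needing
  exact permutation semantics should use the default full-rebuild mode.
* Fisher's exact test beyond 2x2 falls back to chi-square; r x c exact
  tests are not implemented.
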