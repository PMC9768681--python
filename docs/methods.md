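# Methods

`omicstack` implements a two-level ("late integration") strategy for
predicting a binary pregnancy outcome — preeclampsia versus normotensive —
from several longitudinally sampled omics blocks (e.g. urine metabolome,
plasma proteome, cell-free RNA), together with the univariate screens and
correlation networks that accompany such an analysis.  This note records
the model, its assumptions, the tunable parameters, the numerical choices,
and what the synthetic-data experiments do and do not demonstrate.

## The prediction model

**Level one — per-omics elastic net.**  For each omics block with design
matrix `X` (samples × features) and binary labels `y`, coefficients
minimize

    (1/N) Σᵢ [log(1 + exp(ηᵢ)) − yᵢ ηᵢ]  +  λ (α‖β‖₁ + (1−α)/2 ‖β‖₂²),

with η = β₀ + Xβ and the intercept unpenalized.  The mixing parameter is
fixed at α = 0.9: nearly lasso, so a handful of features is selected, with
a small ridge component that spreads weight across correlated features —
appropriate for omics blocks whose effective rank is far below their
width.  The penalty uses the standard path convention `(1−α)/2‖β‖₂²`; the
(1/2) factor and the squared norm are deliberate conventions of the
solver, and the displayed objective is the true negative log-likelihood.
λ is chosen by an internal K-fold cross-validation (stratified by class,
grouped by patient so that repeated samples never straddle an inner
split), minimizing validation binomial deviance over a decreasing
log-spaced grid from λ_max (the smallest λ with an all-zero solution,
computed from the data) down to λ_max·r; following glmnet, r defaults to
10⁻⁴ when samples outnumber features and 10⁻² otherwise.  A
one-standard-error rule is available by flag.  Features are standardized
to zero mean and unit (population) SD using training data only.

**Refit on support.**  Because L1 penalization over-shrinks large
coefficients, the selected support can optionally be refitted by
unpenalized maximum likelihood (`refit=True`), with the support frozen.
An empty support yields the intercept-only model, whose predicted
probability is the class prevalence.  Under complete separation the refit
falls back to a small L2 penalty (λ_ridge = 10⁻³) with a warning.

**Level two — non-negative stacked regression.**  For K blocks, the base
prediction c₋ᵢᵏ(xᵢᵏ) is the block-k score of patient i from a model
trained with *all* of patient i's samples held out.  Stacking weights
solve

    min_γ Σᵢ (yᵢ − Σₖ γₖ c₋ᵢᵏ)²   subject to γₖ ≥ 0,

by the active-set non-negative least-squares method — no intercept, no
sum-to-one constraint.  The leave-one-out construction keeps the
combination honest: each base prediction is an out-of-sample estimate.

**Longitudinal handling.**  Samples taken at different gestational weeks
enter level one as independent observations; the per-sample risk scores of
one patient are averaged (arithmetic mean) into that patient's final risk
score.  Cross-validation folds are defined by patients, never samples.

**Nested evaluation.**  Generalization is estimated by an outer
leave-one-patient-out loop.  Inside each outer training set the entire
machinery — per-block elastic nets with their internal λ cross-validation,
inner leave-one-patient-out base predictions, and the stacking weights —
is retrained from scratch; the held-out patient's samples are then scored
blocks-then-stack and averaged.  No quantity derived from the held-out
patient's features or label enters any training step of their own fold.
Discrimination is summarized by the Mann-Whitney AUC on patient-level
scores with a DeLong asymptotic confidence interval by default
(patient-resampling bootstrap percentile intervals as the alternative;
the interval is truncated to [0, 1]).  A permutation test (patient labels
permuted, full nested pipeline re-run, add-one empirical p-value) is
available for global significance.

## Leave-one-out pooling bias and its correction

Pooling raw leave-one-out probabilities across folds and ranking them, as
an ROC over pooled scores does, is *pessimistically biased*: removing a
case lowers the training prevalence, so the intercept of every fitted
model — and, through the base-prediction matrix, the stacking weights —
encodes the held-out patient's label with the opposite sign.  In the
no-information limit the pooled AUC collapses toward 0 rather than 0.5
(a known pathology of leave-one-out AUC estimation; see Airola et al.,
*Comput. Stat. Data Anal.* 2011).  The default protocol therefore centers
each base-prediction column and the outcome at their training means before
the non-negative least-squares step and applies the same per-block offsets
to the held-out patient's scores.  In the intercept-only limit this makes
all pooled scores exactly equal (AUC 0.5 by the tie convention), and it
leaves genuine signal untouched; stacked risk scores are consequently
*relative* scores rather than probabilities, which is immaterial for
rank-based evaluation.  `debias=False` restores literal raw-probability
stacking.  On null synthetic cohorts (three 50-feature blocks, zero effect
sizes, N = 30) the mean cross-validated AUC is ≈ 0.49 with the correction
and ≈ 0.18 without it.

## Univariate screens

* **Early pregnancy** (samples at or before week 16, earliest sample per
  patient): per-feature two-sample Wilcoxon rank-sum test, exact p for
  combined n ≤ 20 without ties, normal approximation with tie correction
  otherwise.  The signed-rank variant — often conflated with the rank-sum
  test by name — applies only to paired designs and is available via
  `paired=True`.
* **Over gestation**: per-feature linear mixed-effects model
  `value ~ outcome + gestational_week` with a patient random intercept,
  fitted by REML; the reported p is the Wald test of the outcome effect.
  A random slope in week is available by flag.  Non-converging features
  are flagged (p missing) and excluded from the FDR adjustment.
* **Multiplicity**: Benjamini-Hochberg step-up q-values, applied within
  each omics block separately.  No covariate adjustment is performed by
  default — the goal is to capture outcome-associated biology even where
  it overlaps known risk factors such as BMI.
* **Over-representation**: one-sided upper-tail hypergeometric test of a
  selected feature set against user-supplied annotation sets (GMT format)
  over an explicit universe, with BH across sets.  No pathway databases
  are bundled.

## Feature networks

Nodes are features selected during cross-validation, weighted by their
selection frequency (the fraction of outer folds in which the feature
entered the support — a stability measure).  Edges connect pairs with
Spearman ρ above a threshold (default 0.55 on the signed value, as such
networks are conventionally drawn; absolute mode by flag) or by a
k-nearest-neighbor rule (k = 2, neighbors by |ρ|, union over endpoints).
Spearman p-values use the t approximation for n ≥ 10 and an exact
permutation null below (full enumeration up to n = 8).  Graphs export as
edge-list CSV and GraphML; 2-D layout is left to downstream viewers.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
with known ground truth:

* **Geometry**: N patients (default 30), ≈50% case prevalence (cases are
  assigned as exactly `round(N·prevalence)` shuffled patients so every
  seeded cohort supports patient-level cross-validation), 2–3 visits per
  patient with collection weeks drawn uniformly from [5, 16], [17, 28] and
  [29, 38].  Sampling times are outcome-independent by construction.
* **Within-block correlation**: each block is a latent-factor Gaussian,
  `x = L f + shift(y) + ε`, with `n_latent` factors (so the number of
  principal components explaining 90% of variance is ≈ `n_latent`, far
  below the block width, mirroring real multi-omics data).  Factors are
  split between a patient-level and a visit-level component in equal
  variance shares, so repeated samples of one patient correlate.
* **Signal**: `n_signal` randomly chosen features per block are shifted in
  cases by `effect_size` marginal standard deviations, with random signs.
  The ground-truth discriminant is the signal-weighted standardized sum,
  and its attainable AUC is computed by Monte-Carlo simulation from the
  same generative law (`oracle_auc`).
* **Replicates**: the generative law (loadings, signal identities) is
  fixed by the spec seed; `replicate=r` draws an independent cohort from
  that law, e.g. a validation cohort for a trained model.
* **Not emulated**: real analyte identities, assay platforms, batch
  effects, heavy-tailed or compositional distributions, missingness
  mechanisms beyond block-wise missing-completely-at-random.  Passing
  tests on these cohorts demonstrates correctness and calibration of the
  machinery, not clinical performance on real data.

## Numerical choices

* The elastic-net path solver is an iteratively reweighted least-squares /
  coordinate-descent implementation of the glmnet algorithm (numba
  compiled), warm-started along the λ path, with sequential strong rules
  plus a full KKT check (exactness preserved), an active-set inner loop,
  probability clamping at 10⁻⁵, early path termination when the deviance
  falls below 1% of null, and an optional `dfmax` support cap.  Solutions
  agree with a generic numerical minimizer of the penalized objective to
  better than 10⁻⁴ in coefficient sup-norm on low-dimensional problems.
* Fold assignment, λ-grid construction and all seeds derive
  deterministically from one integer seed via seed sequences; outer folds
  may run in parallel with bit-identical results.
* Near-zero-variance filtering uses the frequency-ratio (default 19) plus
  percent-unique (default 10%) rule; thresholds are per-block
  configurable.
* Default problem sizes in the acceptance checks (grid of 25 λ values,
  5 inner folds, coordinate tolerance 10⁻³, support cap 15) are the
  package's single-CPU defaults for cohorts of this scale; `ENConfig`
  defaults remain 100 λ values and 10 folds.
* Missing blocks at prediction time: the remaining stacking weights are
  rescaled to their original total, with a warning.

## Known limitations

* Binary logistic level-one models only; no survival or multinomial
  outcomes.
* The stacked score is a relative risk score, not a calibrated
  probability; no calibration metrics are provided.
* The LME screen's Wald p-values are asymptotic; with very few patients a
  likelihood-ratio or Kenward-Roger correction would be preferable.
* Stacking assumes every training patient has every block; cohorts where a
  block is absent for many patients should drop that block (as was done
  for sparsely measured modalities in the motivating study design).
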