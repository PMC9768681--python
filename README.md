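# omicstack

Multi-omics prediction of preeclampsia by stacked elastic-net models under
nested leave-one-patient-out cross-validation.

Pregnancy cohorts profiled with several omics assays — urine and plasma
metabolome, plasma proteome, cell-free RNA, microbiome — pose a recurring
analysis problem: tens of patients, a handful of longitudinal samples
each, and feature counts ranging from dozens to tens of thousands per
modality, with strong within-modality correlation.  `omicstack` is a
toolkit for building and honestly evaluating sparse predictive models of a
binary pregnancy outcome in this regime, for statisticians and
computational biologists working with such cohorts.

## The method

Per omics block *k*, an **elastic-net logistic model** is fitted by
minimizing

    (1/N) Σᵢ [log(1 + e^{ηᵢ}) − yᵢηᵢ] + λ(α‖β‖₁ + (1−α)/2‖β‖₂²),
    η = β₀ + Xβ,  α = 0.9,

with λ tuned by an internal, patient-grouped cross-validation on binomial
deviance, and an optional unpenalized refit on the selected support.  The
blocks are integrated by **stacked regression with non-negative weights**:
with c₋ᵢᵏ the block-k score of patient *i* from a model trained with all
of patient *i*'s samples held out,

    min_γ Σᵢ (yᵢ − Σₖ γₖ c₋ᵢᵏ)²  s.t.  γₖ ≥ 0.

Longitudinal sample scores are averaged per patient into a final risk
score.  Generalization is estimated by an outer leave-one-patient-out loop
that retrains everything — a **nested (two-level) cross-validation** with
no information flow from the held-out patient (including a correction for
the prevalence-leak bias inherent to pooled leave-one-out scores; see
`docs/methods.md`).  Around the classifier the package provides Wilcoxon
and linear-mixed-effects univariate screens with Benjamini-Hochberg FDR
control, hypergeometric over-representation tests on user-supplied
annotation sets, Spearman correlation networks over selected features, and
a synthetic multi-omics cohort generator with known ground truth used
throughout the test suite.

## Worked example

```python
from omicstack import (BlockSpec, ENConfig, StackedENModel, SyntheticSpec,
                       generate_cohort)

spec = SyntheticSpec(
    n_patients=24,
    blocks=[
        BlockSpec(name="urine_metabolome", p=60, n_latent=5, n_signal=5,
                  effect_size=1.0),
        BlockSpec(name="plasma_proteome", p=40, n_latent=4, n_signal=3,
                  effect_size=0.8),
    ],
    seed=7,
)
cohort, truth = generate_cohort(spec)

cfg = ENConfig(inner_folds=5, n_lambda=25, tol=1e-3, dfmax=15,
               lambda_min_ratio=0.01, seed=7)
model = StackedENModel(cohort, config=cfg)

print(model.cross_validate().summary())
print(model.fit().summary())
```

prints

```
Nested leave-one-patient-out stacked cross-validation
  patients: 24  (cases=12, controls=12)
  AUC = 0.917  95% CI [0.803, 1.000] (delong)
  mean stacking weights: urine_metabolome=1.475, plasma_proteome=0.771
Stacked elastic-net model
  non-negative stacking weights:
    urine_metabolome     gamma=1.5445  support=6 features
    plasma_proteome      gamma=0.7512  support=8 features
```

The cross-validated AUC of 0.917 (DeLong 95% CI [0.80, 1.00]) is the
leave-one-patient-out estimate of how well the stacked score separates
cases from controls; the stacking weights show the metabolome block
carrying most of the integrated signal, consistent with how this cohort
was simulated.  The per-fold selection frequencies recover the planted
biomarkers: the three most stably selected metabolome features
(`f00019`, `f00020`, `f00047`, selected in 100% of folds) are all among
the five true signal features.

The same analysis runs from the shell:

```sh
omicstack simulate --seed 7 --out cohort/ \
    --blocks urine_metabolome:60:5:1.0,plasma_proteome:40:3:0.8
omicstack crossval --in cohort/ --seed 7
omicstack univariate --in cohort/ --block urine_metabolome --test lme
omicstack network --in cohort/ --rho-min 0.55 --out edges.csv
```

or end-to-end from a YAML configuration via `omicstack run --config
analysis.yaml`, which writes score tables, univariate tables, the feature
network and a manifest (seed, config echo, content hashes, warnings) into
an output directory.

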