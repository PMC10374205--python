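# dietclust

Bayesian dietary-pattern clustering and cardiovascular-disease survival
analysis for prospective cohort data.

## The problem

Dietary pattern analysis asks whether the *overall* composition of a diet —
rather than single nutrients — predicts disease. One approach clusters
participants of a cohort study on their food-frequency questionnaire (FFQ)
profiles, labels the resulting clusters (healthy / unhealthy / mixed), and
relates cluster membership to disease incidence with survival models.
`dietclust` implements that full workflow for a cohort design in which
n = 5,396 adults aged 35+ report weekly consumption frequencies of 12 food
groups (fruits, vegetables, dairy, legumes, nuts, white meat, red meat,
processed meat, grain, sweets, hydrogenated and non-hydrogenated vegetable
oils) and are followed 10 years for incident cardiovascular disease (CVD).

Because the underlying individual-level data are not public, the package
ships a calibrated synthetic-cohort generator that reproduces the published
statistical structure — three latent diet clusters at proportions
97 : 4,954 : 345 with their food-profile means/SDs and covariate
distributions, and a proportional-hazards event process calibrated to ~741
events — so every stage is testable end to end.

## The model

**Clustering.** Participants' food-frequency vectors x_i ∈ R^12 are modeled
with a Gaussian Dirichlet-process mixture (DPM), truncated at K components
via its stick-breaking representation:

    v_k ~ Beta(1, α),          w_k = v_k ∏_{j<k} (1 − v_j)
    σ²_kj ~ InvGamma(a₀, b₀),  μ_kj | σ²_kj ~ N(m₀, σ²_kj / κ₀)
    z_i | w ~ Categorical(w),  x_i | z_i = k ~ N(μ_k, diag(σ²_k))

Inference is a blocked Gibbs sampler (allocations → stick fractions →
component parameters → concentration α), with Metropolis label-swap moves
for mixing across component orderings. The concentration α gets a
Gamma(2, 1) prior with the conjugate update
α ~ Gamma(a_α + K − 1, b_α − Σ log(1 − v_k)). By default 1,000 burn-in
iterations are discarded and 20,000 samples retained; per-iteration
allocation probabilities are averaged (after relabeling) and each
participant is assigned to the component with the highest averaged
probability.

**Labeling.** Each occupied component gets a healthfulness score: mean
z-scored intake over the healthy food groups (fruits, vegetables, dairy,
legumes, nuts, white meat) minus the mean over the unhealthy groups (red
meat, processed meat, grain, sweets, oils). Highest score → healthy, lowest
→ unhealthy, the rest → mixed; near-singleton components cannot claim an
extreme label.

**Survival.** The cluster–CVD association is estimated by Cox proportional
hazards — an original implementation of the Efron-tie-corrected partial
likelihood maximized by Newton–Raphson — under four nested adjustment sets:
crude; + age, sex, socioeconomic status (model 1); + smoking, physical
activity, general obesity (model 2); + residency, family history, abdominal
obesity, hypertension, dyslipidemia (model 3). Hazard ratios are reported
with Wald 95% confidence intervals exp(β̂ ∓ 1.96·se).

## Worked example

```python
from dietclust.config import PipelineConfig, GeneratorConfig, DPMConfig
from dietclust.pipeline import run_pipeline

cfg = PipelineConfig(
    generator=GeneratorConfig(seed=11, n_participants=1000),
    dpm=DPMConfig(truncation_K=10, n_burnin=500, n_samples=2000, seed=11),
    collapse_ses=True,
)
report = run_pipeline(cfg, output_dir="demo_run")
print(report.to_text())
```

prints (abridged):

```
dietclust run report (seed=11, n=1000)
occupied components (modal): 5

Cluster sizes:
    healthy: n=57, events=5 (8.8%), censored=52
  unhealthy: n=12, events=2 (16.7%), censored=10
      mixed: n=931, events=121 (13.0%), censored=810

Food-group profiles (mean +/- SD, times/week):
  group                      healthy         unhealthy             mixed
  nuts                 7.60 ± 3.45      2.99 ± 1.30      1.00 ± 0.67
  processed_meat       1.39 ± 0.75      6.23 ± 1.57      0.60 ± 0.41
  ...

Hazard ratios vs healthy cluster (95% CI):
  crude:
    unhealthy: HR 1.859 (0.361, 9.582), p=0.459
        mixed: HR 1.498 (0.613, 3.665), p=0.376
  model3:
    unhealthy: HR 1.873 (0.357, 9.825), p=0.458
        mixed: HR 1.558 (0.630, 3.849), p=0.337
```

The recovered clusters mirror the simulated ones: the healthy cluster is
marked by high nut intake (7.6/wk vs 1.0 in the mixed cluster), the
unhealthy cluster by processed meat (6.2/wk vs 0.6), and the mixed cluster
dominates (n = 931 of 1,000). At this reduced cohort size the unhealthy
cluster holds only 12 people, so its hazard-ratio interval is wide — the
small-cluster warning the pipeline emits. The same pipeline is available
from the shell via the `dietclust` console script
(`dietclust all --config cfg.yaml --out run/`), with each stage
(`simulate`, `cluster`, `label`, `survival`, `report`) re-runnable from
saved intermediates.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly generated cohorts, the two headline hazard-ratio
estimates: the fully adjusted unhealthy-vs-healthy HR (50 replicate cohorts
generated with true HR 2.059 and non-null covariate effects, Model-3 fit)
and the crude mixed-vs-healthy HR (true marginal HR 1.515, no covariate
effects, unadjusted fit), each reported as the mean fitted HR across
replicates. Runs in about a minute on one CPU.
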