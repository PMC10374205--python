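# Methods

This note documents the statistical models implemented in `dietclust`, the
default parameter choices and why they were made, what the synthetic-cohort
generator does and does not emulate, and the known limitations.

## 1. Synthetic cohort generator

The generator (`dietclust.cohort`) produces cohorts with the structure the
analysis assumes; it is first-class, tested code, not a fixture.

**Cluster membership.** Each participant is assigned i.i.d. to one of three
latent diet clusters (unhealthy / mixed / healthy) with default proportions
97/5396, 4954/5396, 345/5396.

**Food-group frequencies** are drawn per dimension from a normal with the
cluster's profile mean/SD (defaults in `dietclust.defaults.PROFILE_MEANS` /
`PROFILE_SDS`), left-truncated at zero by exact truncated-normal sampling.
Truncated normals are used, rather than counts, so that the generator matches
the Gaussian kernel of the clustering stage and parameter recovery stays
interpretable. The *stated* profile parameters are used directly (the
observed mean of a heavily truncated column therefore sits slightly above
its nominal mean — e.g. nuts at 8.1 ± 3.5 yields an observed mean of 8.20;
tests compare against the closed-form truncated-normal mean
μ + σ·φ(a)/(1−Φ(a))). Moment-matching the truncation to the stated moments
is not done for frequencies because it is infeasible for columns whose SD
exceeds their mean (dairy, 0.65 ± 1.6: a left-truncated normal cannot have
SD > mean − bound).

**Age** is the exception: the cohort's entry criterion (35+) means the
published per-cluster age moments describe an already-truncated
distribution, so the underlying normal is moment-matched (2-D root-find on
truncated-normal moments) to reproduce the stated observed mean and SD
exactly. Physical activity is truncated at zero without matching (the shift
is ~3% of the SD). WHR, BMI and serum lipids are plain normals.

**Categorical covariates** (sex, SES, residency, smoking, family history,
hypertension, dyslipidemia) are categorical/Bernoulli draws with per-cluster
probabilities. Dyslipidemia prevalence is not published per cluster; the
default 0.74 in every cluster reflects the high prevalence implied by the
cohort's lipid means against the standard cut-offs (TC ≥ 200, TG ≥ 150,
LDL ≥ 130, HDL ≤ 40/50 mg/dL). Lipid concentrations are generated for
descriptive reporting only and are deliberately *not* linked to the
dyslipidemia flag, which is the only quantity the survival models use.
Obesity flags are derived deterministically: BMI ≥ 30 (general), WHR ≥ 0.90
for men / ≥ 0.85 for women (abdominal).

**Event times** follow an exponential proportional-hazards model: rate
r·exp(η_i) where η_i adds the participant's cluster log hazard ratio
(defaults: log 2.059 unhealthy, log 1.145 mixed, vs healthy) and any
covariate effects (continuous covariates centered: age at 50.67 y, physical
activity at 873.44 MET-min/wk, so exp(η) ≈ 1 on average). Censoring is the
minimum of the 10-year administrative horizon and an exponential dropout
with annual rate 0.013 (matching biennial losses of roughly 3–6% per wave;
dropout is independent of everything, i.e. non-informative). When
`baseline_rate` is left unset it is calibrated by root-finding so the
*expected* number of observed events equals `target_events` (default 741)
for the realized cohort; over seeds 1–20 the realized event count stays
within 10% of 741.

**Confounding toggle.** By default covariate effects are zero, so crude and
adjusted cluster HRs coincide up to noise. `confounding=True` switches in a
realistic preset of covariate log-HRs (age 0.04/y, male 0.30, smoker 0.35,
hypertension 0.60, ...). Because the per-cluster covariate distributions
already differ (the mixed cluster is ~5 years older), non-null covariate
effects alone reproduce the qualitative crude-vs-adjusted attenuation of
the mixed-cluster HR; no separate membership model is required.

**Not emulated:** multistage cluster sampling, biennial interview waves,
item-level (49-item) FFQ data, informative dropout, and any dependence of
diet on covariates beyond the per-cluster distributions. A green recovery
test therefore establishes that the *pipeline* is consistent for data
satisfying its own assumptions — not that the published estimates are
correct for the real cohort.

## 2. Dirichlet-process mixture

`dietclust.dpm` fits a truncated stick-breaking Gaussian DPM with diagonal
component covariances by blocked Gibbs sampling. Full conditionals:

- allocations: P(z_i = k) ∝ w_k ∏_j N(x_ij | μ_kj, σ²_kj), computed in the
  log domain with log-sum-exp normalization;
- sticks: v_k ~ Beta(1 + n_k, α + Σ_{j>k} n_j), k < K;
- components: conjugate normal–inverse-gamma per dimension, empty
  components drawn from the base distribution;
- concentration: α ~ Gamma(a_α + K − 1, b_α − Σ_{k<K} log(1 − v_k)), or
  fixed when `fixed_alpha` is set.

**Defaults and rationale.**

| parameter | default | rationale |
|---|---|---|
| truncation K | 20 | three clusters are expected; 20 leaves headroom at modest cost |
| standardize | on | food-group scales differ by ~20× (grain ≈ 24/wk vs dairy ≈ 0.65/wk); fits are z-scored, summaries back-transformed |
| m₀ | 0 (z-scale) | data centered by standardization |
| κ₀ | 0.01 | vague base measure on component means; large κ₀ puts prior mass for empty components on top of the data and sheds spurious singletons |
| (a₀, b₀) | (3, 3) | prior variance mean 1.5 on the z-scale — weakly informative around the marginal variance |
| (a_α, b_α) | (2, 1) | concentration learned; fixed-α mode available |
| burn-in / samples | 1,000 / 20,000 | analysis-scale schedule; tests use reduced schedules |

**Initialization.** Allocations are initialized by k-means (++ seeding),
relabeled in decreasing size order; `init="random"` is available. Random
initialization is unusable in 12 dimensions: a new component can only be
born from a base-distribution draw that lands near an undiscovered cluster
in *all* dimensions simultaneously, which never happens — with random init
the 1.8% cluster is simply absorbed (verified on exact-Gaussian data).

**Label-permutation moves.** The truncated sampler has a sticky defective
mode: a large cluster that consolidates in the last slot (whose weight is
the stick-breaking remainder) forces all interior sticks small, which
inflates the conjugate α update (α ≈ 6 observed for two clean, well-
separated clusters) and gives empty components enough weight to shed stray
singletons. Two measures remove it: size-descending initialization (big
clusters start in early slots; a big cluster essentially never migrates
backward, so the good mode is absorbing) and Metropolis label-swap moves
each sweep — interior pairs swap contents and sticks with acceptance
min{1, (1−v_{k+1})^{n_k}/(1−v_k)^{n_{k+1}}}; the last pair swaps contents
and redraws its stick from the full conditional, with marginal acceptance
B(1+n_{K−1}, α+n_{K−2}) / B(1+n_{K−2}, α+n_{K−1}). After these fixes the
two-blob benchmark shows exactly two occupied components in ≥ 95% of
retained iterations and α ≈ 0.5.

**Posterior summaries.** Retained iterations are relabeled against running
reference means by greedy nearest-mean matching; component means/variances
are averaged only over iterations at which the component was occupied (so
base-distribution noise from empty components never pollutes them); the
allocation-probability matrix is the average of per-iteration allocation
probabilities; the reported cluster count is the mode of the per-iteration
occupied-component count (occupied = at least one allocated observation).

**Known limitation — truncation skew.** On the default synthetic cohort the
modal occupied-component count is 4–5, not 3. The zero-truncated frequency
distributions are strongly skewed in the low-intake dimensions (mixed
cluster: dairy 0.65 ± 1.6, processed meat 0.3 ± 0.6, nuts 0.6 ± 0.9), and a
Gaussian kernel gains ~70–80 log-likelihood units per extra component by
splitting the dominant cluster — more than the Dirichlet-process prior can
penalize at any plausible concentration (verified with variance priors from
InvGamma(3,3) to InvGamma(20,20), κ₀ from 0.01 to 1, and α fixed from 0.1
to 1; an EM mixture cross-check shows the same likelihood profile, with BIC
preferring 3 but the DP's weaker penalty preferring more). The extra
components are sub-splits of the mixed cluster: the healthy/unhealthy/mixed
*label* partition still recovers the simulated clusters with adjusted Rand
index ≈ 0.95. The corresponding acceptance test is left failing with this
explanation rather than weakened; the pipeline reports occupied counts and
weight traces so the behavior is inspectable.

## 3. Cluster labeling

MAP assignment uses the averaged allocation-probability matrix (not a
single iteration); ties break to the lowest component index and are logged.
The component → {healthy, unhealthy, mixed} map is a reporting convention of
this package (the field labels clusters by inspecting their profiles): each
occupied component is scored by mean z-scored intake over the healthy groups
minus the unhealthy groups; the extremes get the extreme labels and the rest
are mixed. Two guards: (i) score ties break by component index with a
warning; (ii) components MAP-holding fewer than max(2, 0.5% of n)
participants are ineligible for extreme labels — a singleton noise component
otherwise steals "healthy" from a real cluster (observed in testing). The
group partition (grains unhealthy — predominantly refined; all dairy healthy
— fat content unrecorded; white meat healthy, red meat unhealthy) is
config-overridable, and labels should always be reported alongside the
recovered profiles, not taken at face value: simulated "healthy" clusters
eat more red meat and grain than the unhealthy cluster, mirroring their
published profiles.

## 4. Cox proportional hazards

`dietclust.cox` maximizes the Efron-tie-corrected log partial likelihood by
Newton–Raphson from β = 0 with step-halving; convergence when max |score|
< 1e-8 or the relative log-likelihood change < 1e-10 (50-iteration budget);
standard errors from the inverse observed information; Wald CIs and
p-values. Breslow tie handling is available and coincides with Efron on
tie-free data (asserted to 1e-12 in tests). Efron is the default because
rounded real-world follow-up times tie often and Efron is less biased. The
implementation is cross-checked against lifelines (coefficients and SEs to
1e-4) and against brute-force partial-likelihood maximization at n ≤ 8.

Design matrices dummy-code categoricals against a declared first level
(healthy cluster, female, low SES, non-smoker, rural); levels absent from
the data are dropped to keep the design full rank; constant or collinear
columns raise errors naming the column. The nested models are: crude
(cluster only), model 1 (+ age, sex, SES), model 2 (+ smoking, physical
activity continuous and unscaled, general obesity), model 3 (+ residency,
family history, abdominal obesity, hypertension, dyslipidemia).
`collapse_ses=True` recodes SES to low vs not-low: with the default SES
distribution (99%+ low), the moderate/high cells hold ~15 participants and
roughly one synthetic cohort in ten otherwise exhibits monotone likelihood
(zero events in a dummy's cell), which is a property of the data, not a
solver defect. No time-varying covariates or delayed entry; follow-up
starts at baseline for everyone.

## 5. Descriptive statistics

`dietclust.stats` wraps scipy.stats for the table machinery: pooled-variance
(Student) t-test by default with a Welch flag (the pooled form is declared
since only "independent-samples t-test" is specified), Pearson chi-square
without continuity correction, one-way ANOVA, and incidence proportions with
half-up rounding to one decimal. Percentages are reported to 1 decimal,
statistics to 2, p-values to 3. No multiple-testing correction is applied —
a deliberate match to the analysis style being reproduced, and a limitation.

## 6. Numerical and testing notes

- All mixture density arithmetic is in the log domain; allocation rows whose
  densities all vanish raise an error naming the row.
- Stick-breaking weights sum to 1 to ~1e-15 by construction (telescoping);
  tests assert 1e-12.
- Determinism: a single `numpy.random.Generator` seeded from the config
  drives each stage; identical configs give byte-identical cohort CSVs and
  identical posterior summaries.
- Exchangeability is tested at its deterministic core (allocation
  *probabilities* permute exactly with the rows); sampled allocations
  consume a shared RNG stream in row order, so bitwise equality under row
  permutation is not well-defined for a vectorized sampler.
- Reduced MCMC schedules (e.g. 500/2,000) are used in tests to keep the
  suite within minutes; the analysis-scale default (1,000/20,000) is
  unchanged.
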