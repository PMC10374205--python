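"""Default calibration of the synthetic cohort generator.

The defaults describe a 5,396-person prospective cohort of adults aged 35+
followed for 10 years for incident cardiovascular disease (CVD), with three
latent dietary clusters (unhealthy / mixed / healthy) defined on 12 food-group
weekly consumption frequencies from a food-frequency questionnaire (FFQ).

Cluster food-frequency profiles, per-cluster covariate distributions, the
cluster proportions (97 : 4,954 : 345) and the target event count (741) are
the published characteristics of that cohort; they are frozen here so that
every downstream stage (clustering, labeling, survival models) can be
exercised on data with the same statistical structure.
"""

from __future__ import annotations

import numpy as np

#: The 12 food groups, in canonical column order.  HVOs / NHVOs are
#: hydrogenated / non-hydrogenated vegetable oils.
FOOD_GROUPS: tuple[str, ...] = (
    "fruits",
    "vegetables",
    "dairy",
    "legumes",
    "nuts",
    "white_meat",
    "red_meat",
    "processed_meat",
    "grain",
    "sweets",
    "hvos",
    "nhvos",
)

#: Cluster order used everywhere in the generator.
CLUSTER_NAMES: tuple[str, ...] = ("unhealthy", "mixed", "healthy")

#: Cluster sizes 97 / 4,954 / 345 out of 5,396.
CLUSTER_SIZES: tuple[int, ...] = (97, 4954, 345)
N_PARTICIPANTS: int = 5396
TARGET_EVENTS: int = 741

CLUSTER_PROPORTIONS = tuple(n / N_PARTICIPANTS for n in CLUSTER_SIZES)

# Mean weekly consumption frequency (times/week) per cluster and food group,
# rows ordered as CLUSTER_NAMES, columns as FOOD_GROUPS.
PROFILE_MEANS = np.array(
    [
        # fruits veg   dairy legum nuts  white red   proc  grain sweet hvos  nhvos
        [8.4, 6.6, 0.63, 3.2, 1.5, 2.7, 3.7, 5.7, 23.9, 5.7, 9.3, 3.2],   # unhealthy
        [7.4, 6.2, 0.65, 3.03, 0.6, 2.3, 4.1, 0.3, 23.5, 1.8, 8.08, 2.4],  # mixed
        [9.7, 7.4, 1.1, 3.7, 8.1, 2.5, 4.8, 0.8, 24.3, 4.7, 8.5, 2.9],    # healthy
    ]
)

PROFILE_SDS = np.array(
    [
        [5.5, 4.1, 1.9, 2.9, 2.2, 2.5, 2.9, 2.2, 7.7, 7.5, 5.2, 4.6],
        [4.6, 3.8, 1.6, 2.2, 0.9, 2.2, 2.7, 0.6, 6.02, 3.1, 4.8, 3.9],
        [5.7, 4.4, 2.3, 2.7, 3.5, 2.3, 3.07, 1.1, 6.4, 6.1, 5.03, 4.7],
    ]
)

# Per-cluster covariate distributions (unhealthy, mixed, healthy).
# Continuous covariates are (mean, sd) of the *observed* distribution; age is
# additionally left-truncated at 35 (cohort entry criterion) with the
# underlying normal moment-matched so the observed mean/SD equal the targets.
COVARIATE_PARAMS: dict = {
    "age": {"mean": (45.23, 51.07, 46.47), "sd": (9.52, 11.68, 9.74), "lower": 35.0},
    "whr": {"mean": (0.925, 0.93, 0.921), "sd": (0.084, 0.080, 0.089)},
    "bmi": {"mean": (27.65, 26.76, 26.9), "sd": (4.5, 4.7, 4.3)},
    # MET-min/week, truncated at 0 (physical constraint).
    "physical_activity": {
        "mean": (960.01, 867.91, 928.50),
        "sd": (503.64, 548.94, 562.46),
        "lower": 0.0,
    },
    # P(male) per cluster.
    "sex_male": (0.474, 0.489, 0.464),
    # P(family history of CVD).
    "family_history": (0.052, 0.045, 0.058),
    # SES category probabilities (low, moderate, high) per cluster.
    "ses": {
        "levels": ("low", "moderate", "high"),
        "probs": (
            (0.975, 0.025, 0.0),
            (0.993, 0.004, 0.003),
            (0.986, 0.014, 0.0),
        ),
    },
    # P(urban residency).
    "residency_urban": (0.814, 0.724, 0.693),
    # Smoking status probabilities (smoker, ex-smoker, non-smoker).
    "smoking": {
        "levels": ("smoker", "ex-smoker", "non-smoker"),
        "probs": (
            (0.216, 0.072, 0.712),
            (0.153, 0.065, 0.782),
            (0.174, 0.055, 0.771),
        ),
    },
    # P(hypertension).
    "hypertension": (0.082, 0.144, 0.099),
    # P(dyslipidemia).  Not published per cluster; 0.74 reflects the high
    # prevalence implied by the cohort's lipid means against the standard
    # TC/TG/LDL/HDL cut-offs.
    "dyslipidemia": (0.74, 0.74, 0.74),
    # Serum lipids (mg/dL), generated for descriptive reporting only (not
    # linked to the dyslipidemia flag).
    "hdl": {"mean": (45.88, 47.00, 46.21), "sd": (10.28, 10.43, 10.85)},
    "ldl": {"mean": (123.92, 128.6, 127.36), "sd": (44.85, 41.93, 44.45)},
    "tg": {"mean": (208.0, 212.58, 210.9), "sd": (50.05, 49.93, 52.5)},
    "tc": {"mean": (195.42, 192.53, 205.63), "sd": (104.69, 114.59, 171.88)},
}

# Cohort-wide centering constants used in the survival linear predictor so
# that exp(eta) ~ 1 for an average participant and the baseline rate keeps
# its events-per-person-year interpretation.
AGE_CENTER: float = 50.67
PA_CENTER: float = 873.44

# True cluster log hazard ratios vs the healthy reference, from the fully
# adjusted association estimates: HR 2.059 (unhealthy) and 1.145 (mixed).
TRUE_LOG_HRS = {
    "unhealthy": float(np.log(2.059)),
    "mixed": float(np.log(1.145)),
}

#: Realistic non-null covariate effects (log hazard ratios) for scenarios
#: with confounding: magnitudes typical of CVD epidemiology.  Continuous
#: covariates (age, physical_activity) are per-unit on centered scales.
REALISTIC_COVARIATE_LOG_HRS = {
    "age": 0.04,
    "sex_male": 0.30,
    "ses_moderate": 0.0,
    "ses_high": 0.0,
    "smoking_smoker": 0.35,
    "smoking_ex-smoker": 0.20,
    "physical_activity": -2.0e-4,
    "general_obesity": 0.25,
    "residency_urban": 0.15,
    "family_history": 0.40,
    "abdominal_obesity": 0.20,
    "hypertension": 0.60,
    "dyslipidemia": 0.30,
}

#: Annual rate of random loss to follow-up (dropout), events per person-year.
#: Biennial losses of roughly 3-6% per wave over the decade correspond to an
#: annual exponential rate of about 0.013.
DEFAULT_LOSS_RATE: float = 0.013

#: Administrative censoring horizon, years.
DEFAULT_FOLLOWUP_YEARS: float = 10.0

#: Default healthy / unhealthy food-group partition used when mapping
#: discovered components to labels.  Grains count as unhealthy (predominantly
#: refined) and all dairy as healthy (fat content unrecorded).
HEALTHY_GROUPS: frozenset = frozenset(
    {"fruits", "vegetables", "dairy", "legumes", "nuts", "white_meat"}
)
UNHEALTHY_GROUPS: frozenset = frozenset(
    {"red_meat", "processed_meat", "grain", "sweets", "hvos", "nhvos"}
)
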