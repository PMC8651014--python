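"""Default parameters of the synthetic screened cohort.

All values in one place.  Marginal means/SDs and prevalences reproduce the
published predictor summary of a 2.5M-participant vascular-screening
cohort; the *dependence* structure (age/sex slopes
of the comorbidity models, the outcome log-odds) is a synthetic stand-in —
the source reports only marginals and case/non-case contrasts, never a joint
distribution — chosen so the case column is reproduced qualitatively:
an ~8-year age shift, a male excess, elevated heart rate, SBP and weight,
and enrichment of every comorbidity among AF cases.
"""

from __future__ import annotations

#: Overall prevalence of AF on the single screening ECG.
TARGET_PREVALENCE = 0.0041

#: Continuous marginals (mean, SD).  Age is drawn for the *raw* cohort; the
#: exclusion cascade then removes those under 45.
AGE_MEAN, AGE_SD = 64.8, 9.6
AGE_CLIP = (30.0, 95.0)

FEMALE_FRACTION = 0.648
#: smoking categories (current, former, never)
SMOKING_PROBS = {"current": 0.097, "former": 0.306, "never": 0.597}

#: Height sampled by sex so the pooled marginal is ~1.70 +/- 0.10 m.
HEIGHT_BY_SEX = {"female": (1.63, 0.065), "male": (1.78, 0.070)}

#: Body size is generated through BMI — lognormal with mean 27.9 and SD 5.3
#: (BMI is right-skewed, so only ~1% of draws land below the BMI-18
#: exclusion bound); weight follows as BMI * height^2, giving a ~79 +/- 18
#: kg marginal.
BMI_MEAN, BMI_SD, BMI_MIN = 27.9, 5.3, 14.0

#: SBP rises with age; the residual SD is set so the marginal SD is ~19.7.
SBP_MEAN, SBP_AGE_SLOPE, SBP_RESID_SD = 133.0, 0.35, 19.4

#: Resting heart rate; AF cases get an additive shift (irregular, typically
#: faster ventricular response), reproducing the 77 +/- 16.7 case column.
HR_MEAN, HR_SD = 66.0, 10.3
HR_AF_SHIFT_MEAN, HR_AF_SHIFT_SD = 11.0, 13.0

#: Comorbidities cluster within individuals beyond what age and sex explain;
#: a shared standard-normal frailty enters every history model with this
#: loading, concentrating multimorbidity in fewer participants (which also
#: pulls the fraction with CHA2DS2-VASc >= 2 toward the published 52% —
#: the marginals alone pin that fraction near 0.59, a known stand-in gap).
FRAILTY_LOADING = 1.4

#: Comorbidity models: P(history) = expit(a + b_age*(age-65)/10 + b_male*male
#: + FRAILTY_LOADING*u) with the intercept a solved at generation time so the
#: realised marginal matches the target.  (target, age slope per decade,
#: male slope)
HISTORY_MODELS = {
    "hypertension": (0.418, 0.50, 0.10),
    "antihypertensive_medication": (0.434, 0.55, 0.05),
    "diabetes": (0.119, 0.35, 0.20),
    "chd": (0.062, 0.55, 0.70),
    "valvular_disease": (0.040, 0.30, 0.00),
    "chf": (0.009, 0.60, 0.30),
    "copd": (0.034, 0.35, 0.00),
    "pad": (0.037, 0.50, 0.30),
    "stroke_tia": (0.035, 0.55, 0.20),
}

#: Log-odds of prevalent AF per predictor (the generating "truth" of the
#: synthetic outcome).  Continuous terms are centred at the cohort mean so
#: the solved intercept stays near logit(prevalence).
OUTCOME_COEFFICIENTS = {
    "age_per_decade": 0.72,      # on (age - 65)/10
    "male": 0.65,
    "smoking_former": 0.20,
    "smoking_current": 0.00,
    "weight_per_kg": 0.012,      # on (weight - 79.1)
    "sbp_per_mmhg": 0.006,       # on (sbp - 133)
    "hypertension": 0.10,
    "antihypertensive_medication": 0.25,
    "diabetes": 0.20,
    "chd": 0.35,
    "valvular_disease": 0.30,
    "chf": 1.10,
    "copd": 0.35,
    "pad": 0.45,
    "stroke_tia": 0.45,
}

#: Fractions of raw records carrying each pre-screening exclusion flag,
#: matching the published cascade counts relative to the raw total.
EXCLUSION_FRACTIONS = {
    "prior_af_history": 0.0873,
    "no_ecg": 0.1089,
    "sex_inconsistent": 0.0044,
}

#: Default per-variable missingness injected for the imputation stage
#: (the source imputed anything missing in <30%; its per-variable rates are
#: not public, so these are modest plausible self-report/measurement rates).
MISSINGNESS_RATES = {
    "height": 0.04,
    "weight": 0.04,
    "sbp": 0.08,
    "heart_rate": 0.05,
    "smoking": 0.03,
    "hypertension": 0.02,
    "antihypertensive_medication": 0.05,
    "diabetes": 0.02,
    "chd": 0.02,
    "valvular_disease": 0.03,
    "chf": 0.02,
    "copd": 0.02,
    "pad": 0.03,
    "stroke_tia": 0.02,
}
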