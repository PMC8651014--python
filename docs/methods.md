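# Methods

`afscreen` externally validates established risk prediction models for
*prevalent* atrial fibrillation (AF) — AF present on a single screening
12-lead ECG — in large screened populations. This note documents the
statistical procedures, the synthetic cohort that stands in for proprietary
screening data, the numerical choices, and what the tests do and do not
demonstrate.

## Cohort model and exclusion cascade

A cohort is one row per participant with the predictor dictionary of
`afscreen.dictionary`: age (years), sex, smoking status (current / former /
never), height (m), weight (kg), BMI (kg/m², derived), systolic blood
pressure (mmHg), resting heart rate (beats/min), nine self-reported binary
histories (hypertension, antihypertensive medication, diabetes, coronary
heart disease, valvular disease, congestive heart failure, COPD, peripheral
arterial disease, stroke/TIA), pre-screening flags, and the single-ECG AF
outcome. Missingness is one concept — NaN — regardless of source encoding.

BMI is computed from height and weight *before* imputation. The analysis
cohort is then formed by a sequential exclusion cascade in a fixed order:
established AF history → no screening ECG → inconsistent sex recording →
age < 45 → BMI < 18. Each record counts against the first rule it violates,
so the per-rule tallies partition the input; the report exposes the
per-rule counts so an overlapping convention could be compared if needed.
Records with *missing* BMI are retained: imputation, not exclusion, handles
missing anthropometry.

## Synthetic cohort generator

Real screening cohorts of this kind are proprietary, so the generator in
`afscreen.synthetic_cohort` emulates one. All defaults live in
`_cohort_constants.py`:

* **Marginals** reproduce the published predictor summary of a 2.5M
  vascular-screening population: age 64.8 ± 9.6 y, 64.8% female, smoking
  9.7/30.6/59.8%, height ≈ 1.70 ± 0.10 m (sampled by sex), BMI lognormal
  with mean 27.9 and SD 5.3 (right-skewed, so ~1% falls below the BMI-18
  exclusion bound), SBP 133 ± 19.7 mmHg rising 0.35 mmHg/year of age,
  heart rate 66 ± 10.3 bpm, and the nine history prevalences (41.8% down
  to 0.9%).
* **Dependence** is a stand-in, because only marginals and case/non-case
  contrasts are published. Comorbidities follow logistic models in age and
  sex plus a shared standard-normal frailty (loading 1.4) that clusters
  multimorbidity within individuals; each model's intercept is solved at
  generation time so the realised marginal hits its target.
* **Outcome.** AF is drawn from a logistic model on the covariates whose
  intercept is solved by bracketed root finding (to 1e-10) so the mean
  predicted probability equals the target prevalence, 0.41% by default.
  The log-odds coefficients were chosen so the synthetic case column
  reproduces the published contrasts: cases ≈ 8 years older, male excess
  (41–43% of cases female vs 65% of the cohort), elevated weight, SBP and
  comorbidity. Heart rate is shifted upward in cases (+11 bpm with extra
  dispersion) after the outcome draw, reproducing the 77 ± 16.7 case
  column — AF typically presents with a faster, irregular ventricular
  response.
* **Flags and missingness.** Exclusion flags are sampled independently at
  the published cascade fractions. Missingness is injected
  missing-completely-at-random per variable (defaults 2–8%), never on id,
  age, sex, or the outcome, and never at ≥30% (beyond which a variable is
  not considered imputable).

What the generator does *not* emulate: the real joint distribution
(pairwise correlations are unpublished), geographic/temporal structure,
informative missingness, and repeat visits. One visible consequence: with
the published marginals and any plausible dependence, the fraction with
CHA₂DS₂-VASc ≥ 2 lands near 0.60 rather than the published 0.524 — the
age-and-sex points alone pin it there under a (truncated) normal age
distribution. The subset's AF prevalence still reproduces the published
≈0.5%. Passing tests therefore demonstrate correctness of the *pipeline*
under realistic-scale data, not fidelity of any particular joint feature
of the real cohort.

## Multiple imputation

Chained equations (`afscreen.imputation`), with conditional models per
variable kind: Bayesian normal linear regression for continuous variables
(residual variance drawn from its scaled inverse-χ² posterior, coefficients
from their conditional normal — so the m copies carry genuine
between-imputation variability), logistic regression for binary histories,
multinomial logistic for smoking. Categorical conditionals draw the missing
cells at the fitted probabilities without a coefficient-posterior draw — a
documented approximation; predictive-mean matching is deliberately not the
default. The AF outcome predicts in every conditional model but is never
imputed. Missing cells are initialised from observed marginals; variables
are visited in ascending order of missingness fraction (deterministic);
each of the m chains runs a fixed number of sweeps from its own seeded
substream. Conditional fits cap at 20 000 rows (a fresh seeded subsample
per sweep) to keep large-cohort runs tractable on a single core.

Defaults are m = 20 datasets and 200 sweeps, matching a full production
analysis; the bundled end-to-end runs use m = 5 and 10 sweeps (chained
equations on cohorts of this size mix within a few sweeps, and every
result carries its config snapshot). Post-imputation **range rounding**
clamps imputed cells of limited-range variables (SBP 60–260, heart rate
30–220, height 1.2–2.2, weight 30–250, BMI 14–70) to the nearer bound;
observed cells are never touched. BMI is recomputed from the completed
height and weight of each copy rather than imputed directly, keeping the
three consistent (in the rare row where the recomputed BMI itself gets
clamped, consistency yields to the range bound).

**Rubin's rules** (`pool_rubin`): pooled point Q̄ = mean of the m
estimates; within-variance W = mean squared SE; between-variance B = sample
variance of the estimates; total T = W + (1 + 1/m)B; 95% CI from a
t-quantile with ν = (m−1)(1 + W/((1+1/m)B))², degenerating to the normal
quantile when B = 0 (including m = 1).

## Risk models and recalibration

Models are data (JSON/YAML), validated against a pydantic schema: each term
names a predictor, a transform (identity, per-k-units, category indicator,
age band, any-of over binary flags) and either a β-weight (equation models)
or integer points (score charts). Bundled definitions: CHARGE-AF (equation;
simple-model coefficients transcribed from the source publication) and the
CHADS₂, CHA₂DS₂-VASc, HATCH and C₂HEST score charts. Source predictors
absent from the screening dictionary (ethnicity, diastolic blood pressure,
thyroid disease) are carried as `omitted` terms: they contribute nothing
but preserve the published definition; proxies (e.g. CHD history for prior
myocardial infarction) are noted on the term.

Cox-derived linear predictors are pushed through a logistic link with the
slope fixed at 1 — the target is prevalence at a single visit, so baseline
survival is not modelled; the intercept absorbs the scale. That intercept
is **recalibrated** ("calibration-in-the-large") per imputed dataset: with
the slope fixed, the maximum-likelihood score equation reduces to *mean
predicted probability = observed prevalence*, a strictly monotone
one-dimensional condition solved by bracketed root finding to 1e-10.
A consequence used by the tests: the per-participant mean probability
across imputations averages exactly to the cohort prevalence.

The age-threshold comparator ("screen everyone ≥ 65") enters two ways: for
discrimination, as the bare indicator (AUROC is rank-based); for
reclassification, as a two-valued risk model whose values are the AF
prevalences in the two age strata estimated from the analysis data — a
one-parameter intercept fit cannot match both strata, so direct stratum
estimation is the well-defined conversion.

## Discrimination, calibration, screening, reclassification

* **AUROC**: Mann–Whitney estimator (ties one half), SE and paired model
  comparisons by DeLong's structural-components method; per-imputation
  AUROCs pooled by Rubin's rules on the natural scale. The paired
  comparison runs on across-imputation mean predictions; every report
  labels the test.
* **Calibration**: participants ranked by across-imputation mean
  recalibrated probability (stable order on ties), cut into 10 near-equal
  bins; per bin the mean predicted risk and observed prevalence with a
  Wilson 95% interval (well-behaved at prevalences near 0.4%). For score
  charts, observed prevalence by integer sum score instead.
* **Selective screening**: the ⌈q·n⌉ highest-risk participants (stable
  tie-break) form the screened group; sensitivity, specificity, PPV (=
  in-screen prevalence), NPV follow from the 2×2 table. NNS = ⌈1/PPV⌉ — a
  programme cannot screen a fraction of a person; at the published 1.6%
  top-decile prevalence this gives ⌈62.5⌉ = 63.
* **Reclassification vs the age threshold**: IDI = difference in
  discrimination slopes (mean predicted risk cases − non-cases); rIDI =
  IDI / comparator slope; continuous NRI = net proportion of cases moved
  strictly up plus net proportion of non-cases moved strictly down (exact
  ties neutral; bounded in [−2, 2] and invariant to common monotone
  transforms). Uncertainty by nested bootstrap: B participant resamples
  within each imputed dataset, all m·B values pooled *before* taking the
  median and 2.5th/97.5th percentiles (per-imputation medians pooled
  afterwards would understate between-imputation spread); two-sided
  p-value from the pooled distribution's tail proportion at zero, labelled
  as such in output. Resamples that lose an outcome class, or that tie the
  two-valued comparator's slope exactly (rIDI undefined), are redrawn.
* **Subset analyses**: every metric can be restricted to CHA₂DS₂-VASc ≥ 2
  (the anticoagulation-relevant group). The score is computed per imputed
  copy; pooled AUROCs use per-copy masks, and mean-probability metrics use
  the across-imputation majority mask.

## Pipeline and reproducibility

`run_validation` sequences simulate/ingest → BMI → exclusions → imputation
→ per-model metrics → report bundle (JSON + CSV + manifest). One global
seed drives everything; each stochastic stage draws from a substream keyed
by the stage name (CRC-32 into a `SeedSequence`), so changing the bootstrap
size cannot perturb the imputation draws, and two runs of the same config
produce byte-identical bundles. Complete-case mode skips imputation and
analyses rows with no missing predictor; on a cohort with no missingness
it coincides exactly with the m = 1 imputation path.

Run sizes: the bundled end-to-end configuration uses 100 000 raw synthetic
participants (≈78 000 after exclusions), m = 5, 10 sweeps and B = 100 —
sized so a full run completes in about a minute on one core; the test
suite uses smaller cohorts (800–200 000 depending on what the check needs)
with fixed seeds throughout.

## Known limitations

* The generator's dependence structure is a labelled stand-in; see above.
* Categorical imputation omits coefficient-posterior draws, slightly
  understating between-imputation variance for those variables.
* The bootstrap is plug-in: risks and the comparator's stratum prevalences
  are not re-estimated within each resample.
* Percentile bootstrap intervals undercover modestly when the cohort holds
  only a few hundred cases; the null-NRI coverage test documents the scale
  at which they are accurate.
* Score charts have no probability scale, so IDI/NRI (which need risks on
  a common scale) are reported for equation models only.
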