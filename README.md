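# afscreen

External validation of risk prediction models for **prevalent atrial
fibrillation (AF)** in screened populations.

AF carries a five-fold risk of cardioembolic stroke, is often silent, and
is cheap to confirm with a single 12-lead ECG — but its prevalence in the
general screening-age population is only ~0.4%, so unselected screening is
wasteful. Risk prediction models can concentrate screening on the people
most likely to have AF. `afscreen` is a tested pipeline for asking, of any
such model, *how well would it work as a selection tool in a screened
cohort?* It is aimed at biostatisticians and screening-programme analysts.

The pipeline implements the standard external-validation toolkit for a
prevalent (cross-sectional) outcome:

* **Declarative risk models** — regression equations evaluated as
  lp = Σ βⱼ xⱼ and integer score charts — defined as data files, with
  CHARGE-AF, CHADS₂, CHA₂DS₂-VASc, HATCH and C₂HEST bundled;
* **Calibration-in-the-large**: the model intercept α is re-estimated with
  the slope fixed at 1, i.e. α solves mean(expit(α + lp)) = observed
  prevalence;
* **Multiple imputation** by chained equations, with Rubin's rules
  (T = W + (1 + 1/m)B) pooling per-imputation estimates such as the AUROC
  (Mann–Whitney estimator, DeLong standard errors);
* **Decile calibration** tables/plots of observed vs mean predicted risk
  with Wilson intervals;
* **Selective screening** of the top-risk fraction q: sensitivity,
  specificity, PPV, NPV and the number needed to screen, NNS = ⌈1/PPV⌉;
* **Reclassification** against the guideline age ≥ 65 criterion: IDI
  (difference in discrimination slopes), relative IDI, and continuous NRI
  in [−2, 2], with nested-bootstrap percentile intervals;
* a **synthetic cohort generator** that emulates a 2.5M-participant
  vascular-screening population (marginals, case/non-case contrasts,
  0.41% AF prevalence, exclusion flags, MCAR missingness) so the whole
  pipeline is testable without proprietary data.

See `docs/methods.md` for the statistical details and limitations.

## Worked example

```python
import afscreen as a

# a synthetic screened cohort: 50k participants, 0.41% AF prevalence
spec = a.SyntheticSpec(n=50_000, seed=7)
raw = a.generate_cohort(spec)
raw = a.inject_missingness(raw, spec.missingness_rates, seed=8)

# BMI before imputation, then the exclusion cascade
cohort, report = a.apply_exclusions(a.compute_bmi(raw))
print(report.to_dict()["removed"])

# chained-equation imputation, m completed copies
stack = a.impute_chained(cohort, a.ImputationConfig(m=5, iterations=10, seed=9))

# CHARGE-AF: pooled discrimination and top-decile screening yield
models = a.load_model_definitions()
pooled = a.pool_auroc(stack, models["CHARGE-AF"])
print(f"AUROC {pooled.point:.3f} (95% CI {pooled.ci_low:.3f}-{pooled.ci_high:.3f})")

from afscreen.performance import mean_probability_across_imputations
p = mean_probability_across_imputations(stack, models["CHARGE-AF"])
y = stack[0]["af_on_ecg"].to_numpy(float)
res = a.metrics_at_top_fraction(p, y, q=0.10)
print(f"top decile: prevalence {100*res.prevalence_in_screened:.2f}%, "
      f"sensitivity {100*res.sensitivity:.0f}%, NNS {res.nns}")
```

Output (seeds as above):

```
[{'rule': 'prior_af_history', 'n': 4275}, {'rule': 'no_ecg', 'n': 5058},
 {'rule': 'inconsistent_sex', 'n': 182}, {'rule': 'age_below_45', 'n': 743},
 {'rule': 'bmi_below_18', 'n': 430}]
AUROC 0.740 (95% CI 0.703-0.776)
top decile: prevalence 1.96%, sensitivity 40%, NNS 52
```

Reading: after the exclusion cascade, CHARGE-AF separates AF cases from
non-cases with a pooled AUROC of about 0.74; screening only the 10% of
participants at highest predicted risk would find ~40% of all AF cases at
a yield of one case per 52 people screened — versus one per ~244 under
universal screening at 0.41% prevalence.

The same run from the shell:

```bash
afscreen simulate --n 50000 --seed 7 --out cohort.csv
afscreen validate --config run.yaml --out results/   # or defaults
afscreen report --bundle results/                    # calibration/screening SVGs
```

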