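# hccscreen

Claims-based imaging exposure and bias-corrected survival analysis for
hepatocellular carcinoma (HCC) surveillance cohorts.

## The problem

Patients with cirrhosis are advised to undergo semiannual abdominal imaging
so that HCC is caught while still treatable. In administrative claims data
(e.g. Medicare), prediagnostic imaging utilization can be reconstructed from
CPT procedure codes, and survival after diagnosis can be compared across
imaging-exposure groups. Two well-known artifacts make naive comparisons
misleading:

* **Lead-time bias** — screen detection moves diagnosis earlier by the lead
  time, inflating measured post-diagnosis survival even when the disease
  course is unchanged.
* **Length-time bias** — slow-growing tumors spend longer in the
  asymptomatic, screen-detectable phase, so screening preferentially finds
  indolent disease.

`hccscreen` packages the full analysis chain — claims-derived exposure
construction, standard survival modelling, and parametric corrections for
both biases — together with a synthetic cohort generator whose natural
history is fully known, so every stage can be validated against ground
truth (including null scenarios where the true screening benefit is zero).

## What it computes

**Exposure constructs** (per patient, from imaging claims in a 36-month
prediagnostic window, excluding the diagnosis month):

* modality from CPT code: ultrasound (76700, 76705), contrast CT
  (74160, 74170, 74177), MRI (74182, 74183);
* imaging group: CT/MRI (≥1 CT or MRI) > ultrasound (≥1 US, no CT/MRI) > none;
* proportion of time covered, PTC: each exam covers its month plus the six
  following months (truncated at diagnosis); PTC = covered months / 36;
* screen-detected flag: any imaging within 6 months before diagnosis;
* liver-disease etiology by the hierarchy HCV > HBV > ALD > others > NAFLD,
  with a metabolic surrogate rule for under-coded NAFLD;
* early stage: single tumor ≤ 5 cm, no vascular invasion, no metastasis.

**Survival machinery**: Kaplan–Meier with Greenwood variance and
complementary log-log CIs, log-rank test, Cox proportional hazards (Efron
ties) in the two study specifications (imaging group with no-imaging
reference; PTC per 10 percentage points of coverage), Aalen–Johansen
cumulative incidence, and a Fine–Gray subdistribution-hazard model via IPCW
risk-set expansion.

**Lead-time correction** (exponential sojourn with rate λ): the expected
lead time of a screen-detected patient is

* dead at `t`:  `E[s | s ≤ t] = (1/λ)·[1 − (1+λt)e^(−λt)] / (1 − e^(−λt))`
* alive at `t`: `E[min(s, t)] = (1/λ)·(1 − e^(−λt))`

and is subtracted from that patient's observed survival. Base case mean
sojourn 1/λ = 6 months; sensitivity analyses at 3 and 9 months.

**Length-time adjustment**: with slow-tumor prevalence `w_s` among
screen-detected and `w_c` among symptomatic patients and relative risk of
death θ for slow vs aggressive tumors, the expected ratio of death
probabilities under no true benefit is
`R0 = [1 − w_s(1−θ)] / [1 − w_c(1−θ)]`; the corrected relative risk is
`φ = (δ1/δ2) / R0`. Six scenarios (slow proportion 10/20/30% × θ 0.8/0.9)
feed a sensitivity grid of 1-/3-/5-year survival per imaging group.

## Worked example

Simulate a null-benefit cohort (no true screening effect, homogeneous
6-month sojourn, no stage shift), then watch the lead-time artifact appear
and get removed:

```python
from hccscreen import (CohortConfig, SojournModel, apply_exclusions,
                       apply_lead_time_correction, fit_cox, generate_cohort)

config = CohortConfig(n_patients=20000, seed=1, slow_fraction=0.0,
                      slow_theta=1.0, true_screening_log_hr=0.0,
                      stage_shift_prob_screen=0.15, stage_prob_clinical=0.15,
                      other_cause_hazard_per_month=0.0)
cohort = generate_cohort(config)
screen = (cohort.truth["detection_mode"] == "screen").to_numpy()
analysis, n_excluded = apply_exclusions(
    cohort.patients.assign(screen=screen.astype(int)))

uncorrected = fit_cox(analysis, covariates=["screen"])
sojourn = SojournModel.from_mean(6.0)
corrected = apply_lead_time_correction(
    analysis, analysis["screen"].to_numpy(bool), sojourn)
fit = fit_cox(corrected, covariates=["screen"],
              time_col="corrected_time_months")
```

Output:

```
excluded 593 patients with 0-month follow-up
uncorrected screen-vs-clinical HR: 0.857 (95% CI 0.820-0.895)
lead-time-corrected HR:         1.009 (95% CI 0.965-1.055)
```

The uncorrected model reports a ~14% mortality reduction for screen-detected
patients that is entirely lead-time artifact (the generator gave screening
zero true benefit); after subtracting the expected lead time the hazard
ratio is compatible with 1.

## Command line

```bash
hccscreen simulate --n 5000 --seed 11 --out cohort/
hccscreen analyze --patients cohort/patients.csv --imaging cohort/imaging.csv \
    --sojourn-months 6 --slow-prop 0.2 --theta 0.9 --out reports/
hccscreen analyze ... --exposure-window -7:-1     # short-window sensitivity
hccscreen analyze ... --include-zero-month        # re-include 0-month rows
```

`analyze` emits exposure.csv, descriptive_table.csv, ptc_histogram.csv,
km_curves.csv (unadjusted and lead-time-adjusted, per group),
model_results.csv (Cox and Fine–Gray, both specifications),
cumulative_incidence.csv, sensitivity_grid.csv and a manifest with the
configuration hash.

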