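# Methods

## Natural-history model

Each synthetic patient carries a latent tumor history. A preclinical phase
begins at a continuous calendar onset time; its duration (the sojourn, the
window in which the tumor is asymptomatic but screen-detectable) is
exponential with rate λ per month. A fraction `1 − q` of tumors
(`slow_fraction`, default 0.2) belong to a slow-growing class whose mean
sojourn is multiplied by `slow_sojourn_multiplier` (default 2.0) and whose
HCC-death hazard is multiplied by θ (`slow_theta`, default 0.9). The sojourn
multiplier is the mechanism that produces length-biased screen detection:
longer preclinical windows catch more exams, so the slow class is enriched
among screen-detected cancers.

Imaging arrives in two monthly streams: semiannual surveillance (a patient
is enrolled with probability `surveillance_enrollment`, attends each
scheduled slot with probability `surveillance_adherence`) and a Poisson
stream of other abdominal imaging (`diagnostic_imaging_rate` per month;
claims cannot distinguish intent, so both streams are generated). Each exam
inside the preclinical window detects the tumor independently with a
modality-specific sensitivity (defaults 0.5 for ultrasound and 0.85 for
CT/MRI, reflecting ultrasound's limited sensitivity for early HCC); the
first success fixes screen detection at that exam's month. Otherwise the
tumor surfaces clinically at the end of its sojourn.

Internally, onset and surfacing times are continuous while exams sit on the
integer month grid. This matters: with a continuous exponential sojourn,
memorylessness makes the residual sojourn at the detecting exam — the lead
time — exactly Exp(λ), which is the premise of the parametric correction.
Discretizing the sojourn to whole months first would turn the residual into
a geometric variable with mean ≈ 1/λ + 0.5 and inject a systematic
half-month error into every lead-time experiment. The claims layer
(imaging months, diagnosis month, follow-up) is reported at whole-month
granularity, as in Medicare data; follow-up is floored to integer months,
and deaths in the diagnosis month yield the 0-month rows that the exclusion
rule operates on.

## Survival construction

The latent HCC-death clock starts at clinical surfacing: observed time from
diagnosis is `lead + Exp(h_hcc)` where
`h_hcc = baseline · exp(Σ β·x + log(θ)·slow + γ·screen)` with covariate
effects β (`log_hazard_effects`), the slow-class effect θ, and a true
screening effect γ (`true_screening_log_hr`, default 0). Other-cause death
is exponential from diagnosis (`other_cause_hazard_per_month`), and
administrative censoring occurs `admin_censor_months` (default 60) after
diagnosis. Under γ = 0, θ = 1 and no stage shift, screen and clinical
patients share the same true post-surfacing mortality, so any fitted
difference on observed times is pure lead-time artifact — this is the
construction the null-recovery checks exploit.

Covariate marginals (sex, age, race-free demographics, comorbidity,
etiology mix, cirrhosis/ascites/encephalopathy, early-stage fraction,
group sizes, median survival near 15 months, roughly a quarter of deaths
from non-HCC causes, sparse imaging coverage) emulate a contemporary
elderly US Medicare HCC cohort. Etiology flags are generated so that the
claims-side hierarchy (HCV > HBV > ALD > others > NAFLD, with the metabolic
surrogate rule for under-coded NAFLD) reconstructs the latent category
exactly; tumor size/extent fields are generated consistently with the
latent early-stage flag so the stage classifier is exercised end to end.

## Exposure constructs

Month arithmetic is calendar-month based with diagnosis at month 0 and
prediagnostic months negative; imaging in the diagnosis month is excluded.
PTC gives each exam 7 months of coverage (its month plus six), truncated at
month −1, and divides the union of covered months by the fixed 36-month
window. The denominator is never rescaled: the cohort is defined by three
years of continuous enrollment, so a shorter window is a validation error,
not a renormalization. The screen-detected claims flag (any imaging in
[−6, −1]) deliberately misclassifies some truly screen-detected patients:
the detecting exam often falls in the diagnosis month and is excluded, just
as in real claims. Mechanism-validation tests therefore take the truth
table's detection mode, while the pipeline uses the claims flag — the
distinction is intentional and documented in the report tables.

## Lead-time correction

For screen-detected patients the expected lead time is subtracted from
observed survival: `E[s | s ≤ t]` for patients dead at `t` and
`E[min(s, t)]` for patients censored at `t`, both under `s ~ Exp(λ)`
(base-case mean 6 months; sensitivity 3 and 9). Both expressions are
strictly below `t`, so corrected times stay positive without clamping (the
code asserts rather than floors), and they are kept as reals for KM/Cox
input — re-flooring would only add ties. A series expansion replaces the
dead-case ratio below λt = 1e−5 where the direct expression loses
precision; its t→0 limit is t/2.

The correction is exact for the lead-time component but deliberately
parametric: it conditions only on follow-up time and vital status, not on
the (unobservable) joint law of lead time and post-surfacing survival. Two
residual artifacts remain outside its scope and are visible in the
generator when enabled: (i) the 0-month exclusion removes more clinical
than screen-detected patients (clinical patients can die in the diagnosis
month; screen-detected patients rarely can, their lead time pushing death
later); (ii) with nonzero other-cause mortality, screen-detected patients
spend their lead time exposed to other-cause death after diagnosis — an
overdiagnosis-flavoured contamination. The null-recovery experiment
therefore uses HCC-only mortality, which is the configuration in which the
observed difference is pure lead-time artifact.

## Length-time adjustment

The slow/fast mixture identity: with slow prevalence `w_s` among
screen-detected and `w_c` among symptomatic patients and death-risk ratio
θ, the expected observed death-probability ratio under no true benefit is
`R0 = [1 − w_s(1−θ)] / [1 − w_c(1−θ)]`, and `φ = (δ1/δ2)/R0`. `w_s, w_c`
are not identified from data; they derive from an assumed overall slow
proportion `1 − q` and an enrichment mode subject to
`p·w_s + (1−p)·w_c = 1 − q`:

* **maximal** (default for the scenario grid): slow tumors fill the
  screen-detected stratum up to feasibility, `w_s = min(1, (1−q)/p)` — a
  conservative bound;
* **proportional**: the slow-class odds among screen-detected equal a
  configurable factor times the odds among symptomatic patients (solved by
  bisection).

Six scenarios (slow proportion 0.1/0.2/0.3 × θ 0.8/0.9) define the
sensitivity grid. Survival curves are adjusted by dividing each interval's
conditional death probability by R0 (capped at 1) and recomposing the
product limit; adjustment applies only to strata containing screen-detected
patients, so the no-imaging group is invariant by construction. When both
corrections are requested, lead-time correction precedes length-bias
adjustment.

In the φ self-consistency experiment, δ1 and δ2 are all-cause death
probabilities within 24 months on lead-time-corrected follow-up. All-cause
(rather than HCC-specific) probabilities are used because cause-specific
death by a fixed horizon is additionally distorted by competing-cause
preemption during the lead time, which is not length bias; 24 months keeps
the hazard-ratio-to-risk-ratio gap small (the identity treats θ as a risk
ratio, the generator applies it to the hazard; at this horizon and these
hazards the discrepancy is below 0.01). The matching scenario uses
proportional enrichment with the realized slow-class odds ratio between
detection strata, because the generator's enrichment is mechanistic (via
the sojourn multiplier), not an assumption to be guessed — the experiment
validates the mixture identity itself.

## Survival machinery

Kaplan–Meier, the log-rank test, and Cox regression (Efron tie handling —
month-granular data make ties pervasive, and Efron is the less biased
approximation) are delegated to lifelines behind this package's interfaces;
Greenwood variance is computed alongside, and KM confidence intervals use
the complementary log-log transform to stay inside [0, 1]. Medians are
flagged (not raised) when survival never reaches 0.5. The two model
specifications are: imaging group with no-imaging reference, and both PTC
terms jointly, each scaled so one unit is 10 percentage points of coverage.
Constant covariates are dropped and reported rather than fatal.

The Aalen–Johansen cumulative incidence estimator is implemented directly
(`CIF_k(t) = Σ_{s≤t} S(s−)·d_k(s)/n(s)`): the available library estimator
jitters tied event times, which would break the exact reduction
`CIF = 1 − KM` on month-granular data that the tests assert at 1e−10.

The Fine–Gray subdistribution model is implemented as IPCW (Geskus-style)
risk-set expansion: subjects failing from a competing cause remain at risk
with weight `G(t−)/G(T−)` from the censoring-distribution Kaplan–Meier.
Extended risk is split at censoring-time jumps of G rather than at every
event time of interest — the weight is a step function constant between
jumps, so the weighted partial likelihood is identical while the expansion
stays compact under administrative censoring. The weighted
counting-process fit (entry/exit rows, subject-clustered robust sandwich
variance) is delegated to the Cox solver. The implementation is verified
against R's `cmprsk::crr` on a fixture in the test suite, and reduces to
the cause-specific Cox model (to 1e−6) when no competing events exist.

The 0-month exclusion removes deaths in the diagnosis month before
modelling; the sensitivity variant re-includes them at 0.5 months (the
half-month convention is configurable).

## Problem sizes and numerical choices

Validation experiments use: 10⁶ exponential draws for the lead-time
Monte-Carlo oracle (agreement required within 0.5% relative); 50 replicate
cohorts of n = 20,000 for null-benefit recovery; n = 50,000 for the φ
experiment; 1,000 random event sets for exact PTC enumeration; n = 20,000
for Cox parameter recovery (±3 SE); n = 5,000 for the end-to-end
determinism run. The bisection for proportional enrichment uses xtol 1e−12;
the small-n Cox oracle solves the score equation by bisection and matches
the iterative fit at 1e−4 (the solver's own convergence tolerance).

## Design choices made where the design was open

* Confounding by indication (sicker patients receiving more imaging) is not
  generated by default; covariates and imaging intensity are independent.
  The exposure–covariate association observed in real claims is therefore
  absent, and regression adjustment in the synthetic pipeline is exercised
  but not stressed.
* The generator's survival layer is intentionally simple (constant
  cause-specific hazards given covariates) so that proportional-hazards
  fits are well specified and parameter recovery is checkable.
* Same-month multi-modality claims pose no ordering problem: group
  assignment is by presence of any CT/MRI in the window, so ties are moot.
* The report pipeline embeds a hash of the analytic configuration (output
  location excluded) in every table, so grid outputs are traceable to their
  assumptions.

## What passing tests do and do not show

The synthetic cohort reproduces the structural features the methods depend
on — monthly claims, exponential sojourn, a slow/fast mixture, stage shift,
competing mortality, administrative censoring — but not real Medicare claim
layouts, ICD code strings, day-level timing, enrollment gaps, or
confounding by indication. Green tests demonstrate that the exposure
constructs match their definitions exactly, that the survival machinery
agrees with independent oracles, and that the bias corrections recover
known truth under their own model; they do not certify the corrections
against misspecification in real data (e.g. non-exponential sojourn), where
the sensitivity grid over sojourn means and mixture scenarios is the
intended tool.
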