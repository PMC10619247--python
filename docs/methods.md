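# Methods

## The risk-adjustment model

The unit of analysis is the hospitalization, not the patient: case-mix
adjustment underpins payment per admission, and the same patient may be
admitted repeatedly.  Each hospitalization is described by 30 dichotomous
Elixhauser comorbidity indicators derived from its own ICD-9-CM diagnosis
codes (codes recorded at a patient's *other* admissions never count).  Four
outcomes are modeled separately on that indicator matrix:

| outcome | type | model |
|---|---|---|
| in-hospital death | binary | logistic |
| escalation of care | binary | logistic |
| 30-day readmission | binary | logistic |
| log length of stay | continuous | OLS |

Coefficients are re-derived on each dataset (the Elixhauser approach supplies
code definitions, not fixed weights).  The cohort is split 70/30 at random by
hospitalization into derivation and validation sets; models are fit on the
derivation set by maximum likelihood / least squares with an always-included
intercept, and the frozen coefficients are then applied unchanged to the
validation set.  Discrimination is summarized by the c-statistic (binary
outcomes) or R² (log LOS, with validation R² defined as 1 − SSE/SST about the
validation mean); calibration by the Hosmer–Lemeshow decile test.  No
regularization, no multiple-testing adjustment, and no clustering correction
for repeat patients are applied; patients may straddle the split (a
documented caveat, matching the hospitalization-level design).

## Comorbidity flagging rules

* **Normalization.** Raw codes are trimmed, upper-cased, and stripped of the
  dot; the leading `V`/`E` selects the namespace.  Malformed codes are logged
  and contribute no flags.
* **Range matching.** A definition token compiles to an inclusive interval at
  the precision of its printed endpoints.  A recorded code is truncated to
  that precision when longer and right-padded with zeros when shorter; ranges
  whose endpoints print at different precisions (e.g. `042–044.9`) are
  normalized by right-padding the shorter endpoint.  This reproduces the
  intended category spans and captures 5-digit children of 4-digit entries,
  the standard convention for administrative data.
* **Hierarchies.** If both diabetes flags are set, only complicated diabetes
  counts; if both tumor flags are set, only metastatic cancer counts.  The
  operation is idempotent and only ever clears flags.
* **Hypertension** is a single combined condition whose patterns are the
  union of the uncomplicated and complicated sub-lists.
* **DRG screen.** Each condition carries a list of diagnosis-related groups
  in which it would be the principal disease; when enabled, a flag is cleared
  if the hospitalization's DRG falls in that list.  The screen is **off by
  default**: the analysis this package operationalizes did not apply it, and
  Israeli extracts carry no DRG.  It is implemented and switchable for
  completeness, and passes the profile through unchanged (with a one-time
  warning) when the DRG is absent.
* **Default exclusion.** Blood-loss anemia is excluded from modeling by
  default, reproducing the 29-condition analysis in which that condition was
  nearly empty (6 cases) and would destabilize the fits.  A `min_count`
  option can additionally drop any condition below a chosen carrier count;
  it defaults to 0 (exclusion is explicit, not automatic).

## Outcome definitions

* **Escalation of care** is a composite: any ICU stay; any intermediate-care
  (IMCU) stay (included by default, switchable — the composite is sometimes
  quoted without IMCU); mechanical ventilation; BiPAP delivered in the
  daytime band, the half-open interval [08:00, 20:00), since night BiPAP may
  treat sleep-disordered breathing rather than impending respiratory
  failure; or receipt of one of seven vasopressors (adrenaline, dobutamine,
  dopamine, milrinone, noradrenaline, phenylephrine, vasopressin), compared
  case-insensitively after trimming.  Death and escalation are not mutually
  exclusive.
* **30-day readmission** is any subsequent admission of the same patient
  (elective included, same facility only) whose admit is strictly after the
  discharge with a calendar-date gap ≤ 30 days; the boundary is inclusive and
  configurable.  No censoring correction is applied for deaths or for
  hospitalizations discharged near the end of the observation window — they
  simply count as non-readmissions, a known limitation shared with the
  original analysis.
* **Length of stay** is discharge minus admit in fractional days; zero-length
  stays are rejected (undefined under the log).  The natural log is used
  throughout; the base only rescales coefficients, and generator and recovery
  tests share it.

## Numerical choices

* Logistic fits use Newton/IRLS (statsmodels) with an L-BFGS fallback; Wald
  standard errors come from the observed information.  Complete or
  quasi-complete separation — plausible here because some conditions are very
  rare (AIDS/HIV prevalence < 0.1% keeps this path realistically exercised) —
  is detected as a zero cell in a predictor's 2×2 table with the outcome and
  is *reported*, not repaired: the model returns `converged=False` and a
  warning naming the columns.  An explicit option to drop unstable columns
  (`min_count`) exists but is off by default.
* The c-statistic is computed from midranks (Mann–Whitney form), crediting
  score ties 1/2; it equals trapezoidal AUROC to floating-point precision and
  is invariant under strictly increasing score transforms.
* Hosmer–Lemeshow groups are formed by cutting at quantiles of predicted
  probability with tied probabilities never split across groups (so group
  sizes are unequal in tie-heavy data); duplicate quantile boundaries are
  collapsed, and df = (effective groups − 2).  The variance term is the
  grouped-binomial form E_g(1 − E_g/n_g).  A group whose expected count is 0
  or equals its size raises with the suggestion to use fewer groups.
  Calibration is reported on the validation set under the frozen derivation
  coefficients (external calibration); derivation-set calibration can be
  obtained by passing the derivation data to `hosmer_lemeshow` directly.
* The 70/30 split is simple (unstratified) uniform sampling without
  replacement, deterministic in a required, logged seed.

## The synthetic cohort generator

The generator defines the study conditions under which the pipeline is
exercised; its defaults are the published characteristics of the cohort it
emulates and are not tuned per run.

* **Flags** are independent Bernoulli draws at the cohort's observed
  prevalences (e.g. congestive heart failure 27%, hypertension 46%, fluid and
  electrolyte disorders 13%, AIDS/HIV 0.03%), except that complicated
  diabetes is drawn as a sub-split of "any diabetes" and metastatic cancer of
  "any cancer", making the severity hierarchies hold by construction.
  Comorbidity *correlations* are not modeled — the source reports marginals
  only, so independence is an explicit modeling choice; a consequence is
  that synthetic c-statistics sit somewhat below the real-data values (less
  clustering of risk), which is why discrimination levels themselves are not
  acceptance quantities.
* **Codes** realizing a true flag are drawn uniformly from the condition's
  expanded code set, with codes that would collide with another condition
  removed from the pool, so an emitted code can never activate a false flag;
  ~30% are emitted undotted to exercise normalization, and Poisson(2) "noise"
  codes matching no condition are added per record.  Emitted codes are
  syntactically valid category/subcategory strings; no claim is made that
  every enumerated code exists in the official ICD-9-CM tabular list.
* **Binary outcomes** are drawn from logistic models whose per-condition
  log-odds are the natural logs of the published odds ratios for this
  population, with intercepts found by 1-D root-finding (Brent) on the
  realized linear predictor so the marginal rates hit 6.9% (mortality), 13%
  (escalation) and 15% (readmission).  Outcomes are independent given the
  flags, mirroring the separately fitted models.
* **log LOS** = baseline + X·β + Gaussian noise, with β the published
  log-day effects.  The noise SD defaults to
  `sqrt(Var(Xβ)·(1−R²)/R²)` at R² = 0.10, placing the linear model in the
  observed explanatory-power regime, and the baseline to
  `ln(4.1) − mean(Xβ)` so the median stay is ≈ 4.1 days.  Ages follow a
  piecewise-linear quantile curve with median 74 and IQR (61, 84).
* **Escalation labels** are realized as concrete mechanisms chosen uniformly
  (ICU stay, IMCU stay, ventilation event, daytime-BiPAP event, or a named
  vasopressor); if a stay is too short to contain a daytime moment the
  mechanism falls back to ventilation.  Non-escalation records receive
  decoys (night BiPAP, the non-listed oral pressor midodrine) at low rates;
  decoys never flip labels.
* **Readmission labels** are realized as admission chains: a readmitted
  record is followed by the same patient's next admission after a 1–30 day
  gap; a non-readmitted record either ends the chain or (15% of the time)
  continues after a 31–90 day gap.  A few extra admissions may be appended
  beyond `n` to close the final chain.  Chains never overlap in time.
* All timestamps are rounded to whole seconds and ground-truth LOS is
  recomputed from the rounded timestamps, so recomputed outcomes equal the
  ground truth exactly.  A single seeded generator drives everything;
  identical config + seed yields byte-identical output files.

What passing tests on this generator do and do not show: they verify the
mapping, outcome, modeling and evaluation machinery end to end, including
parameter recovery at derivation-set size (39,162 records) — but real
hospital data have correlated comorbidities, coding-intensity artifacts, and
secular trends that the generator deliberately omits, so performance numbers
on synthetic cohorts are not forecasts of real-data performance.

## Problem sizes used in the test suite

Simulation-based checks run at the sizes the design targets: Hosmer–Lemeshow
type-I error at the validation-set size (16,784) over 200 replicates;
derivation/validation stability at the full cohort size (55,946); parameter
recovery at the derivation size (39,162) over three seeds in the test suite
and ten in `scripts/acceptance.py`; code-matching oracle comparisons over
10,000 random codes.

## Known limitations

* Independence of comorbidities (a Gaussian-copula correlation hook is a
  natural extension; marginals-only calibration was chosen deliberately).
* Readmissions at other facilities are invisible; no competing-risk handling
  of death before readmission.
* ICD-9-CM only; no ICD-10/11 mappings, no AHRQ/Quan variants, no van
  Walraven summary weights.
* The DRG screen's named groups are reconstructed from the published group
  labels; with the screen off by default this affects nothing unless enabled
  against DRG-bearing data.
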