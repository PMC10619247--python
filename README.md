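# casemix

Elixhauser comorbidity risk adjustment for internal-medicine hospitalizations.

Internal-medicine admissions are often reimbursed per diem, with no account of
how sick the patients are — hospitals that treat more complex patients get no
extra payment.  The standard remedy is case-mix (risk) adjustment: score each
hospitalization by its comorbidity burden and model the outcomes that matter.
`casemix` implements the complete analytical chain for doing this with the
freely available 30-condition **Elixhauser index** on ICD-9-CM coded data, as
used to risk-adjust internal-medicine hospitalizations in settings (such as
Israeli hospitals) that still code diagnoses in ICD-9-CM and lack a DRG-based
payment system.  It is aimed at health-services researchers and hospital
analysts who need a tested, reproducible pipeline rather than one-off scripts.

## What it does

1. **Comorbidity flagging** (`casemix.icd9`, `casemix.elixhauser`) — compiles
   the published ICD-9-CM code lists (single codes and ranges such as
   `428.0–428.9`) into interval patterns and assigns 30 dichotomous condition
   flags per hospitalization.  Matching follows administrative-data
   convention: a recorded code is truncated to the pattern's precision (so a
   4-digit table entry captures its 5-digit children) or zero-padded when
   shorter.  Severity hierarchies (complicated diabetes over uncomplicated,
   metastatic cancer over solid tumor) and an optional DRG screen are applied
   afterwards.
2. **Outcome construction** (`casemix.outcomes`) — four dependent variables
   per hospitalization: in-hospital death; *escalation of care* (ICU or
   intermediate-care stay, mechanical ventilation, daytime BiPAP between
   08:00 and 20:00, or a named vasopressor); readmission within 30 days of
   discharge (same facility, inclusive boundary); and length of stay in days,
   modeled as log LOS to correct right skew.
3. **Modeling** (`casemix.modeling`) — a random 70/30 split into derivation
   and validation sets; per-outcome models on the 0/1 comorbidity design
   matrix (logistic for the binary outcomes, OLS for log LOS), reported as
   odds ratios / β with Wald 95% CIs, with the derivation coefficients then
   forced unchanged onto the validation set.
4. **Evaluation** (`casemix.evaluation`) — discrimination by the c-statistic
   (tie-aware concordance, equal to the area under the ROC curve) or R², and
   calibration by the Hosmer–Lemeshow grouped chi-square
   `H = Σ (O_g − E_g)² / (E_g (1 − E_g/n_g))` over risk deciles, with
   (groups − 2) degrees of freedom.
5. **Synthetic cohorts** (`casemix.synthetic`) — a seeded generator that
   emits raw records (diagnosis codes, ward stays, treatment events,
   readmission chains) with configurable comorbidity prevalences, true
   per-condition effects, and calibrated marginal outcome rates, plus
   ground-truth labels, so the whole pipeline is testable end to end without
   access to protected hospital data.

## Worked example

Run the full pipeline on a synthetic cohort of 20,000 hospitalizations:

```bash
casemix run --n 20000 --seed 1 --out demo_run
```

which prints

```
mortality: c = 0.672 (derivation), 0.654 (validation)
escalation: c = 0.649 (derivation), 0.626 (validation)
readmission: c = 0.582 (derivation), 0.586 (validation)
log_los: R^2 = 0.093 (derivation), 0.102 (validation)
artifacts in demo_run
```

Each line is one outcome model fitted on the 70% derivation set; the second
number applies the frozen derivation coefficients to the held-out 30% — the
two agreeing closely is the check that the models are not overfitted.
Discrimination is moderate by construction: comorbidity flags alone explain
only part of outcome variation (readmissions are hardest to predict, log-LOS
R² ≈ 0.10).  `demo_run/` then contains `prevalence.csv`,
`coefficients_<outcome>.csv` (OR or β, 95% CI, significance stars),
`models.json`, `evaluation.json` (c/R² for both sets plus the
Hosmer–Lemeshow decile table — here, mortality H = 12.96 on 8 df, p = 0.11,
i.e. no calibration problem), `summary.json` (cohort characteristics:
median age 73.9 with IQR 61.0–83.9, median LOS 4.1 days, mortality 6.8%…),
and a `manifest.json` stamping every artifact with the config hash and seed.

The library surface mirrors the CLI; the same analysis in Python:

```python
from casemix import (GeneratorConfig, RunConfig, run_pipeline)

cfg = RunConfig(out_dir="demo_run",
                generator=GeneratorConfig(n=20_000, seed=1))
result = run_pipeline(cfg)
print(result.reports["mortality"].c_validation)
```

`casemix generate` writes a raw synthetic cohort (three EMR-style CSVs plus
ground truth) that `casemix map`, `casemix outcomes`, `casemix summarize` and
`casemix run --data DIR` can consume; real extracts in the same layout work
identically.

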