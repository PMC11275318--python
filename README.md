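# dynapred

Dynamic overall-survival prediction for an osteosarcoma-like cohort via a
proportional landmark supermodel with time-varying covariates (local
recurrence, new metastatic disease) and a time-varying histological-response
effect. Because the motivating trial data are not publicly available, the
package ships a synthetic multistate cohort generator with known ground
truth, so the entire pipeline — stacking, fitting, prediction, validation,
multiple imputation and pooling — is exercised end to end without any data
download.

## What's inside

| module | purpose |
| --- | --- |
| `dynapred.cohort` | patient-table schema, reference-coded covariate encoding, CSV I/O |
| `dynapred.simulate` | synthetic cohort generator: marginal covariate frequencies, covariate-dependent LR/NM onset, piecewise-constant death hazard with status effects, censoring, MCAR masking |
| `dynapred.stacking` | eligibility filters, landmark grid (default 0–5 y by 3 months, 5-year window), stacked counting-process dataset, risk-set counts |
| `dynapred.supermodel` | pseudo partial likelihood (delayed entry, Breslow ties, Newton with step-halving), cluster-robust sandwich covariance, Breslow baseline, hazard-ratio table |
| `dynapred.prediction` | time-varying hazard ratio `HRCON × HRLIN^tp × HRQUAD^(tp²)` with delta-method CIs, CI crossing time, conditional window death probabilities per profile × disease status |
| `dynapred.validation` | heuristic shrinkage `(χ²−p)/χ²`, sliding-window dynamic C-index (leave-one-out or fast), reverse Kaplan–Meier median follow-up |
| `dynapred.imputation` | multiple imputation of tumor volume (log-normal) and histology (probit latent threshold), Rubin's-rules pooling |

## CLI

```bash
dynapred simulate --n 2000 --seed 1 --out cohort.csv
dynapred stack    --cohort cohort.csv --out stack.csv --counts-out counts.csv
dynapred fit      --stack stack.csv --out-fit fit.json --table-out hr_table.csv
dynapred predict  --fit fit.json --profiles profiles.csv --out curves.csv
dynapred validate --cohort cohort.csv --times 0,1,2,3,4,5 --fast --out report.json
dynapred impute   --cohort cohort.csv --m 10 --seed 1 --out-dir imps/
dynapred pool     --fits fits/ --out pooled.json
```

`simulate --config` accepts a YAML file with `truth:` overrides (hazard
rates, log effects, censoring) and `frequencies:` (per-covariate category
probabilities). Profile CSVs for `predict` use the cohort schema; each row
is expanded across the four disease statuses (none / LR / NM / LR+NM).

## Notes

- The generative onset/censoring processes are documented stand-ins chosen
  to reproduce realistic marginal event frequencies; the published analysis
  reports death-hazard effect sizes but no generative model.
- Published absolute 5-year death probabilities depend on the unavailable
  cohort's baseline hazard and are reproduced qualitatively (ordering,
  monotonicity), never numerically.
- All reported confidence intervals default to the cluster-robust (by
  patient) sandwich variance; model-based variance is also computed and
  serialized.
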