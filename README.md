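# cogrci

Control-referenced reliable-change analysis of perioperative cognitive
outcomes, with a synthetic-cohort simulator, covariate-adjusted association
models, and cohort-flow reporting.

A seven-parameter neuropsychological battery (PAL memory score, VRM free
recall, VRM delayed recognition, SSP span, grooved pegboard time, simple
reaction time, trail-making B time) is carried on a common oriented scale —
timed measures are log-transformed and reversed so that higher is always
better.  A non-surgical control cohort tested twice supplies per-parameter
means/SDs of retest change (practice effects and natural variability) and of
baseline level.  Subjects are z-scored against those moments with
deterioration oriented positive, and flagged as impaired when the composite
z (sum of per-parameter z's rescaled by the control SD of that sum) exceeds
1.96 or when at least two individual parameters do.  Baseline levels yield a
preoperative-impairment label (preCI); pre-to-post change yields the
3-month postoperative-dysfunction label (POCD).  Logistic models then relate
the labels to thalamus volume (OR per cm³, Wald 95% CI), adjusted for age,
sex and intracranial volume, with ROC-AUC and VIF diagnostics.

## Layout

| module | contents |
|---|---|
| `cogrci.battery` | battery definition, orientation/log transforms, trail-making timeout rule, change-vector assembly |
| `cogrci.simulate` | synthetic control + surgical cohorts with known ground-truth impairment, item-level missingness, YAML config |
| `cogrci.rci` | control reference fitting, z-scoring, two-clause dichotomization, null false-positive-rate Monte Carlo |
| `cogrci.models` | logistic/OLS fits, Mann–Whitney ROC AUC (DeLong variance optional), VIF screen, composite standardization |
| `cogrci.report` | flow ledger, half-up percentages, characteristics tables, group boxplots |
| `cogrci.pipeline`, `cogrci.cli` | stage wiring and the `cogrci` command |

## CLI

```sh
cogrci --seed 1 --outdir out simulate     # assessments/covariates/truth CSVs
cogrci --seed 1 --outdir out classify     # outcomes.csv + control_reference.json
cogrci --seed 1 --outdir out associate    # model_results.csv + model_report.txt
cogrci --seed 1 --outdir out report       # flow ledger, characteristics, boxplot
```

A YAML config mirroring `SimulationConfig` field names can be passed with
`--config`; `--seed` overrides the config seed.

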