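# kidbank

Psychometric calibration and validation for birth-to-five caregiver-report
child-development item banks.

Population-level surveys of early child development pool items from
several caregiver-report instruments into one large item bank (here ~200
items), administer each child only the ~40 items appropriate for their age
in months, and score everyone on a common latent scale. `kidbank`
implements the full analysis such a study needs, on synthetic data with
known ground truth or on your own CSV tables:

* **Calibration** — graded-response IRT model with a latent regression of
  ability on an age spline, fitted by EM marginal maximum likelihood:
  `Pr(Y_j >= k | theta) = expit(alpha_j (theta - delta_jk))`,
  `theta ~ N(x'gamma, 1)`. Structural missingness from age windows is
  handled by the marginal likelihood, no imputation needed.
* **Scoring** — expected-a-posteriori (EAP) ability and its conditional
  standard error of measurement (CSEM, the posterior SD) per child.
* **Reliability** — marginal reliability
  `r = Var(eap) / (Var(eap) + mean(csem^2))` and the age-conditional
  reliability `r_i = 1 - csem_i^2 / Var(eap | age_i)`, with the
  age-conditional variance from a spline location-scale model and a
  per-month curve checked against a cutoff (default .80).
* **Invariance** — differential-item-functioning screen across groups
  (likelihood-ratio tests with anchor purification, Benjamini-Hochberg
  FDR) and a sensitivity analysis testing whether freeing DIF items
  changes group-mean conclusions (Wald chi-square with bootstrap
  covariance).
* **Validity** — age-adjusted ("part") correlations with concurrent
  instrument scores, and criterion regressions (log income, caregiver
  education, race/ethnicity, PHQ-2/GAD-2 distress) with chained-equations
  multiple imputation pooled by Rubin's rules (Barnard-Rubin df).
* **Synthetic data** — a seeded generator reproducing the study structure:
  ages 0-71 months, 197-item bank averaging 39 administered items,
  ability rising ~4 SD with age, standardized criterion effects, MCAR
  covariate missingness (7.2% income, 10.8% PHQ/GAD), optional DIF
  injection, concurrent-score stand-ins.

The API follows the statsmodels idiom: model classes
(`GradedResponseModel`, `LocationScaleModel`, `MultigroupGRM`) built from
data whose `fit()` returns results objects carrying estimates,
uncertainties, diagnostics and `summary()`; thin functions (`fit_grm`,
`score_eap`, `detect_dif`, ...) wrap them. See `docs/methods.md` for the
models, assumptions, and design choices.

## Worked example

```python
import numpy as np
from kidbank import (GeneratorConfig, generate_dataset, fit_grm,
                     fit_location_scale, conditional_reliability,
                     part_correlation, impute, criterion_regression)

cfg = GeneratorConfig(n_children=2000, n_items=80, mean_admin_items=25,
                      seed=7)
ds = generate_dataset(cfg)
ages = ds.covariates.table["age_months"].to_numpy(float)

res = fit_grm(ds.responses, ds.item_bank, ages)
scores = res.score()
rep = conditional_reliability(scores, fit_location_scale(scores))
pc = part_correlation(scores.eap,
                      ds.covariates.table["d_score"].to_numpy(float),
                      ages, x_name="ability", y_name="d_score")
pooled = criterion_regression(
    scores, impute(ds.covariates, m=10, seed=7, scores=scores),
    blocks=["race_ethnicity", "phq_gad"])

print(f"calibrated {ds.item_bank.n_items} items in {res.n_cycles} EM cycles "
      f"(converged={res.converged}, loglik={res.loglik:.1f})")
print(f"discrimination recovery r = "
      f"{np.corrcoef(res.params.alpha, ds.true_params.alpha)[0,1]:.3f}")
print(f"marginal reliability      = {rep.marginal_r:.3f}")
print(f"mean conditional (child)  = {rep.mean_conditional_r_children:.3f}")
print(f"min conditional           = {rep.min_conditional_r:.3f} "
      f"at {rep.age_at_min} months")
print(f"age-adjusted r with concurrent stand-in = {pc.r:.3f} ({pc.verdict()})")
h = pooled.get("race_ethnicity[hispanic]")
p = pooled.get("phq_gad_total")
print(f"hispanic contrast = {h['estimate']:.3f} (SE {h['total_se']:.3f})"
      f"   [generated: -0.237]")
print(f"phq/gad per-unit  = {p['estimate']:.3f} (SE {p['total_se']:.3f})"
      f"   [generated: -0.128]")
```

which prints:

```
calibrated 80 items in 195 EM cycles (converged=True, loglik=-31294.0)
discrimination recovery r = 0.973
marginal reliability      = 0.967
mean conditional (child)  = 0.921
min conditional           = 0.865 at 0 months
age-adjusted r with concurrent stand-in = 0.895 (ideal)
hispanic contrast = -0.221 (SE 0.058)   [generated: -0.237]
phq/gad per-unit  = -0.111 (SE 0.011)   [generated: -0.128]
```

Reading the output: the fitted discriminations correlate .97 with the
generating values; overall score reliability is .967 but only .865 for
newborns relative to same-age peers (the marginal statistic flatters the
instrument because ability rises steeply with age); the age-adjusted
correlation with a concurrent-instrument stand-in clears the .70 "ideal"
convergent-validity threshold; and the pooled criterion regressions
recover the generated Hispanic (-0.237 SD) and caregiver-distress
(-0.128 SD/unit) effects within sampling error, with the imputation noise
folded into the SEs.

## Command line

Each stage is a subcommand over the library:

```bash
kidbank simulate --seed 1 --out run/data
kidbank calibrate --responses run/data/responses.csv \
    --bank run/data/item_bank.csv --children run/data/children.csv \
    --out run/params.json
kidbank score --params run/params.json --responses run/data/responses.csv \
    --bank run/data/item_bank.csv --children run/data/children.csv \
    --out run/scores.csv
kidbank reliability --scores run/scores.csv --out run/reliability.json
kidbank dif --responses run/data/responses.csv --bank run/data/item_bank.csv \
    --children run/data/children.csv --grouping race_ethnicity \
    --out run/dif.json
kidbank run-all --config pipeline.yaml   # end-to-end with a manifest
```

Input schemas (UTF-8 CSV, header row, empty cell = missing):

| file | columns |
|---|---|
| item_bank.csv | item_id, source_instrument, domain, n_categories, age_min_months, age_max_months |
| responses.csv | child_id, item_id, response (0-based) |
| children.csv | child_id, age_months, income, education, race_ethnicity, phq1, phq2, gad1, gad2, optional score columns |

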