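# tvmiss

**Missing outcomes and time-varying confounders in marginal structural
models: multiple imputation vs inverse probability weighting.**

Comparative-effectiveness studies of *sustained* treatment strategies
(biologic drugs in rheumatoid arthritis registries, for example) face two
entangled problems: time-varying confounding — the disease-activity score
that drives next period's treatment choice is itself affected by past
treatment — and missing data in the patient-reported outcomes and
confounders, both intermittent ("non-monotone") and through drop-out.
`tvmiss` is a tested simulation laboratory for this setting, aimed at
biostatisticians choosing between the two standard repair strategies:

* **IPW**: censor each person at their first missing observation, model
  the probability of remaining observed, and multiply the stabilized
  inverse-probability-of-missingness weights into the treatment weights;
* **MI**: multiply impute the missing outcomes/confounders by chained
  equations (linear, logistic or predictive-mean-matching imputers), run
  the weighted analysis per completed dataset, and pool with Rubin's
  rules.

Either way the causal analysis is an IPTW-weighted marginal structural
model for the end-of-follow-up outcome,

    E[Y^ā] = α + Σ_{t≥1} β_t a_t ,      SW_T = Π_t P(A_t | Ā_{t-1}, B) / P(A_t | Ā_{t-1}, X̄_t, Ȳ_{t-1}, B) ,

with the always-vs-never treatment effect `ATE = Σ_t β_t` (true value
0.2 in the shipped generating model, −0.2 in its skewed-outcome
variants).  Total weights multiply `SW_T` by the analogous stabilized
missingness ratios.  See `docs/methods.md` for the full generating
model, estimators and design choices.

## Worked example

`analysis/02_single_dataset_demo.py` simulates one registry-style cohort
(n = 5000, five visits, 25% intermittent missingness plus 25% drop-out)
and analyzes it every way:

```
simulated n=5000, realized missingness: 25.7% intermittent + 23.8% drop-out
  complete_data_reference  ATE = +0.2039  (model SE 0.0665)
  IPW                      ATE = +0.1137  (model SE 0.1663)
  MI_linear                ATE = +0.2565  (model SE 0.1083)
  IPW bootstrap 95% CI: [-0.1613, +0.4171] (200 resamples, 7s)
  (true ATE of the generating model: +0.20)
```

All three estimates are consistent with the true effect of +0.20, but the
spread differs sharply: the complete-data reference (no missingness, the
best achievable) has SE 0.07; MI recovers most of that precision
(SE 0.11) because it keeps all 5000 people in the analysis; IPW pays for
censoring everyone after their first missing visit with an SE more than
twice as large — on a single dataset its estimate can land far from the
truth, as here.  The simulation grids quantify exactly this trade-off:

```python
import tvmiss as tv

spec = tv.ScenarioSpec(name="nm_both_high", pattern="nm_both", level="high",
                       n=1000, n_reps=200, m_imputations=10)
result = tv.run_scenario(spec, methods=["IPW", "MI_linear"])
print(result.performance[["method", "bias", "emp_se", "rmse"]])
```

Typical output: both methods' bias is within a few hundredths of zero,
while `rmse(IPW) / rmse(MI) ≳ 2` in the high non-monotone cells.

The numbered drivers under `analysis/` run the full factorial — normal
outcome (4 missingness patterns × 2 levels), right-skewed outcome
(linear MI vs PMM), and misspecification (omitted confounder
interaction) — and write per-scenario performance tables (bias,
empirical SE, rMSE, each with Monte Carlo SEs) under `results/`.

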