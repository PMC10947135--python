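# Methods

`tvmiss` studies how to handle missing outcomes and missing time-varying
confounders when estimating the effect of a *sustained* (time-varying)
treatment with inverse-probability-of-treatment-weighted marginal
structural models (MSMs).  Two strategies are compared on identical
simulated registry-style cohorts:

* **IPW** — handle the missing data with inverse probability of
  missingness weights (IPMW) multiplied into the treatment weights, after
  censoring each person at their first missing observation;
* **MI** — handle the missing data with multiple imputation by chained
  equations, fit the weighted MSM inside each completed dataset, and pool
  with Rubin's rules.

## Generating model

Each person is followed over `T = 5` visits `t = 0..4`.  Baseline
covariates are a rare binary marker `B_bin ~ Bernoulli(0.06)` and an
age-like continuous covariate `B_cont ~ 18 + 72·Beta(5, 3)` (mean 63,
SD 11.6); `B_cont` enters all equations standardized by its theoretical
moments (`b_std`), so its mean-zero property is exact, not estimated.
Within a visit the causal order is `X_t → A_t → Y_t`:

| equation | form | defaults |
|---|---|---|
| confounder | `X_t = γ_A A_{t-1} + 0.5 X_{t-1} + 0.3 b_std + 0.3 B_bin + ε_x` | `γ_A = −0.2`, `sd(ε_x) = 0.866` (`X_0`: sd 1) |
| treatment | `logit P(A_t=1) = −1.1 + 1.8 A_{t-1} + 0.5 X_t − 0.4 Y_{t-1} + 0.25 b_std + 0.4 B_bin` | `A_0 ≡ 0` |
| outcome | `Y_t = δ_A A_t + δ_L A_{t-1} − 0.4 X_t − 0.25 b_std − 0.3 B_bin + ε_y` | `δ_A = 0.04`, `δ_L = 0.02`, `sd(ε_y) = 1` |

Treatment is decided from the previous treatment, the current confounder
and the most recent outcome (`Y_{t-1}`): the outcome measured at a visit
follows the treatment decision, so the current outcome cannot enter the
treatment equation; analysts' treatment models condition on the same
history, keeping the weight models correctly specified.

The estimand is the always-treat vs never-treat contrast in the mean
end-of-follow-up outcome `Y_4`.  Because every structural equation is
linear with additive noise, the per-person counterfactual contrast under
common random numbers is deterministic, and the oracle
(`true_ate_oracle`) returns the true ATE with essentially zero Monte
Carlo error.  The defaults satisfy

    ATE = δ_A + δ_L + (−0.4)·γ_A·(1 + 0.5 + 0.25) = 0.06 + 0.14 = 0.20

exactly; `calibrate_ate` re-solves the common effect multiplier for any
other target (the ATE is linear in that multiplier).  The skewed-outcome
variants flip the effect signs (true ATE −0.2) and replace `ε_y` by a
zero-mean, unit-variance shifted log-normal, `sd(log) = 0.5` (skewness
≈ 1.8) or `1.0` (skewness ≈ 6.2): the conditional *mean* structure — and
hence the MSM — stays correct while the residual law is right-skewed.

### Missingness

Only `X_t` and `Y_t` at visits `t ≥ 1` can be missing; treatment and
baseline data are always recorded.  Two mechanisms coexist, mirroring
registry patterns:

* **monotone drop-out** `C_t`: an absorbing discrete-time hazard that
  blanks both variables from the drop-out visit onwards;
* **non-monotone (intermittent) gaps**: per-visit blanking of the
  outcome (`nm_outcome`), the confounder (`nm_confounder`), both jointly
  (`nm_both`), or each independently (`mixed`), applied at visits not yet
  dropped out.

Every logit depends on *lagged* quantities only
(`A_{t-1}, X_{t-1}, Y_{t-1}, B`) — never on current values — so
missingness is MAR by construction with respect to the current cells
(verified by a regression test: given the lagged history, the indicator
does not load on the pre-blanking current value).  One caveat is shared
with any lag-driven mechanism: a lagged predictor may itself have been
blanked at the previous visit, in which case the realized mechanism is
MAR with respect to the underlying (not the observed) history.

Scenario levels set marginal targets over person-visits `t ≥ 1`: 10%
("low") or 25% ("high"), applied separately to the non-monotone and the
drop-out components.  `calibrate_missingness_intercepts` solves for the
intercepts by bracketed root search on the *expected* proportions
computed analytically on a fixed 40 000-person calibration cohort
(survival products for drop-out; blanking probability among survivors
for the intermittent part), so calibration is deterministic and cached.
Realized proportions land within ±1 percentage point at n = 30 000.

### Misspecification scenarios

A `b_std · X_t` interaction is added to the true outcome equation (and
its lagged analog to the missingness logits) while the analysts' models
omit it.  Its coefficient is deliberately small (0.015 "low" / 0.03
"high"): the induced MI bias responds near-linearly to the coefficient
(slope ≈ 0.27 outcome units per unit coefficient at n = 1000), and these
values place the omitted-interaction bias at roughly 2% and 4% of the
true effect — the degree of misspecification the scenarios are meant to
probe.  Because `b_std` has exactly zero mean, the interaction leaves
the true marginal ATE at 0.2.

## Estimators

**Treatment weights.** Pooled logistic models over visits 1–4 (visit
indicator terms included).  Denominator: `A_t ~ A_{t-1} + X_t + Y_{t-1}
+ B_cont + B_bin`; numerator: `A_t ~ A_{t-1} + B_cont + B_bin`.  The
stabilized weight is the cumulative product of numerator/denominator
probabilities of the realized treatment; the baseline visit contributes
ratio 1 (`A_0` is deterministic).  No truncation is applied.

**Missingness weights (IPW path).** The panel is first *monotonized*:
each person is censored at their first visit with any unobserved cell,
so a single "still observed" process remains.  A discrete-hazard pooled
logistic is fitted among persons observed at the previous visit —
denominator `O_t ~ A_{t-1} + X_{t-1} + Y_{t-1} + B` (+ visit terms),
numerator `O_t ~ A_{t-1} + B`.  Total weights multiply the stabilized
treatment and missingness weights; the machinery accepts separate
outcome/confounder indicators for user data, but after monotonization
they coincide.  If nothing is missing the hazard models collapse to
constant probability one, which makes the IPW and MI pipelines exactly
identical on complete data (a tested reduction identity).

**MSM.** Weighted least squares of `Y_4` on `(A_1, …, A_4)` with HC0
robust covariance; the ATE is the sum of the four treatment
coefficients.  Because the stabilized numerators condition on the
baseline covariates, the outcome regression adjusts for `(B_cont,
B_bin)` as well — in the stabilized pseudo-population treatment remains
associated with baseline covariates, and omitting them reintroduces
confounding (empirically: sum of coefficients ≈ −0.49 instead of 0.20
at n = 4·10⁵).  With no effect modification in the model the adjustment
terms leave the ATE contrast untouched.

**MICE.** Wide (person-level) chained equations: each incomplete column
`X_t`/`Y_t` is regressed on *all* other columns (baseline covariates,
the full treatment history, and every other visit's measurements), so
past and future information enters each imputation — the standard layout
for longitudinal MI.  Each of the `M` imputations is an independent
chain: parameters are drawn properly (`σ²* = σ̂²(n−k)/g`, `g ~ χ²(n−k)`;
`β* ~ N(β̂, σ²*(XᵀX)⁻¹)`) before filling in.  Variables are updated in
time order; with linear-Gaussian conditionals and that sweep order the
chains equilibrate within two or three sweeps, so the default burn-in is
5 sweeps (configurable; a monotone-drift heuristic warns if means are
still trending after six or more).  Continuous variables use the normal
linear imputer; `MI_PMM` switches the outcome columns to predictive mean
matching with `q = 5` donors, ties at the q-th distance included.  PMM
uses type-1 matching (donor means from `β̂`, target means from `β*`),
which showed less finite-sample attenuation of the treatment contrast
than scoring both sides by `β*`.  Per completed dataset the full
weight-plus-MSM analysis is re-run; the `M` ATEs are pooled by Rubin's
rules `V = W + (1 + 1/M)B` (estimates are pooled, never weights).

**Bootstrap.** `bootstrap_ci` resamples persons and reruns an arbitrary
pipeline (default 1000 resamples, percentile 95% interval).  It is meant
for single-dataset analyses; the simulation harness relies on model SEs
because a nested bootstrap is computationally out of reach.

## Simulation harness

Per replication one cohort is generated, missingness imposed once, and
the identical incomplete data are analyzed by every method, alongside a
complete-data stabilized-weight reference that guards the
generator/estimator pair.  Seeds derive from
`SeedSequence(base_seed, spawn_key=(replication,))`, making every
estimate bit-reproducible from the scenario specification alone (the
`RunManifest` records the config hash and master seed).  Failures are
recorded per replication, never raised; a scenario with more than 5%
failed replications is flagged invalid.

Performance per scenario × method: mean estimate, bias, empirical SE and
rMSE, each with its Monte Carlo standard error (bias: `empSE/√R`; empSE:
`empSE/√(2(R−1))`; rMSE via the delta method).  The identity
`rMSE² = bias² + empSE²·(R−1)/R` holds exactly row by row.

### Problem sizes

The full study design is 1000 replications of n = 5000 with M = 50
imputations per scenario.  The package's reproduction runs — the
acceptance script, the acceptance tests and the default settings of the
`analysis/` drivers — use desk-scale twins: **n = 1000, 200
replications, M = 10**.  At that scale the Monte Carlo SE of a mean ATE
estimate is roughly 0.005–0.015 (2.5–7.5% of the true effect, largest
for IPW in high non-monotone cells), so all bias checks carry an
explicit 2-MC-SE allowance.  Expected qualitative findings at either
scale: both methods approximately unbiased for a normal outcome; IPW's
rMSE at least twice MI's when non-monotone missingness is high (censoring
discards most of the sample and the total weights are highly variable).
In those harshest cells the censoring-based IPW estimator additionally
shows a small finite-sample bias at n = 1000 (on the order of a tenth of
the true effect, with heavy-tailed replication estimates) that
disappears at n = 5000 — the usual small-sample behavior of highly
variable inverse-probability weights, and the reason the bias checks at
desk scale lean on their Monte Carlo allowances.  Further findings:
linear-imputation MI slightly biased but within 8% of the truth under a
skewed outcome, with PMM no worse; MI bias of a few percent under the
omitted-interaction misspecification, still with lower rMSE than IPW.

## What the generator does and does not emulate

It emulates the structural features that drive the methods comparison:
treatment confounded by a lagged-feedback time-varying covariate,
outcomes and confounders missing intermittently and by drop-out at
registry-like rates, baseline data complete, treatment always recorded.
It does not emulate: bounded/ceiling-effect outcomes (quality-of-life
scales), measurement error, effect modification, long-range direct
treatment effects (`A_t → Y_{t+k}, k > 1`), informative visit timing, or
missingness depending on current values (MNAR).  Passing tests therefore
demonstrate correctness of the estimators under MAR with a correctly
specified mean structure — not robustness to those further
complications.

## Numerical choices

* Logistic fits use a dedicated vectorized IRLS (deviance tolerance
  1e-10, separation flagged when fitted log-odds exceed ±30), validated
  against statsmodels GLM; the harness fits ~25 pooled logistics per
  replication and per-fit overhead would otherwise dominate.
* Rank-deficient imputation designs drop collinear columns (QR with
  pivoting) with a warning rather than aborting.
* Positivity is asserted empirically: treatment prevalence must stay
  inside (0.05, 0.95) at every post-baseline visit; constant treatment
  columns in the MSM abort with a positivity diagnostic.
* Noiseless imputation models (`σ̂² = 0`) short-circuit to deterministic
  draws instead of dividing by a χ² draw.
* Missing cells travel as NaN with explicit observation indicators; CSV
  round-trips use `%.17g` and pandas' round-trip float parser so panels
  survive serialization bit-exactly.

## Known limitations

* The IPW path assumes monotonized missingness; genuinely non-monotone
  IPMW constructions are out of scope.
* MNAR sensitivity analysis, doubly robust estimators, g-computation and
  repeated-measures MSMs (a per-visit outcome mode exists for users but
  is not part of the reproduction runs) are not implemented.
* The lag-driven missingness mechanism is MAR with respect to the
  underlying history; when a lagged predictor was itself unobserved the
  observed-data MAR condition holds only approximately (shared by design
  with the study being emulated).
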