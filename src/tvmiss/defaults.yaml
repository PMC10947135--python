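# Shipped generating-model coefficients.
#
# Effects are calibrated so the intervention-defined true ATE equals the
# target (verified by the oracle test to within 0.002):
#   direct  y_on_a + y_on_a_lag                    = 0.06
#   mediated y_on_x * x_on_a_lag * (1 + g + g^2)   = 0.14   (g = x_on_x_lag)
# The skewed-outcome variants flip the effect signs (target ATE -0.2) and
# replace the Gaussian outcome noise with a zero-mean unit-variance shifted
# log-normal (sd(log) = 0.5 low skew / 1.0 high skew).
#
# The misspecification interaction (b_std * x) is calibrated against the
# harness itself: omitting it from the imputation models moves the MI
# estimate of the ATE by about 2% (low) / 4% (high) of the true effect
# (bias responds near-linearly to the interaction coefficient, slope
# ~0.27 outcome units per unit coefficient at n = 1000).  The companion
# missingness-mechanism coefficient keeps the same low:high ratio.

coefficients:
  baseline:
    b_bin_prev: 0.06          # prevalence of the rare binary covariate
    b_cont_a: 5.0             # Beta shape a (age-like, right-heavy)
    b_cont_b: 3.0             # Beta shape b
    b_cont_lo: 18.0
    b_cont_hi: 90.0
  confounder:
    x0_sd: 1.0
    intercept: 0.0
    a_lag: -0.2               # treatment lowers future disease activity
    x_lag: 0.5
    b_std: 0.3
    b_bin: 0.3
    sd: 0.866
  treatment:
    intercept: -1.1
    a_lag: 1.8                # treatment persistence
    x: 0.5                    # higher disease activity -> more likely treated
    y_lag: -0.4
    b_std: 0.25
    b_bin: 0.4
  outcome:
    intercept: 0.0
    a: 0.04
    a_lag: 0.02
    x: -0.4                   # disease activity lowers quality of life
    y_lag: 0.0                # autoregressive outcome term (off by default)
    b_std: -0.25
    b_bin: -0.3
    sigma: 1.0
  missingness:                # logit slopes of being missing / dropping out
    a_lag: 0.4
    x_lag: 0.3
    y_lag: -0.3
    b_std: 0.2
    b_bin: 0.3

skew_effects:                 # overrides for the skewed-outcome scenarios
  y_on_a: -0.04
  y_on_a_lag: -0.02
  x_on_a_lag: 0.2

target_ate:
  normal: 0.2
  skew_low: -0.2
  skew_high: -0.2

misspec_interaction:
  low:  {outcome: 0.015, missingness: 0.02}
  high: {outcome: 0.03, missingness: 0.04}
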