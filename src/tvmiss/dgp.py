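"""Synthetic longitudinal cohorts with time-varying confounding and MAR missingness.

The generating model mimics a disease-registry setting: a binary treatment
``A_t`` (e.g. a biologic drug) chosen at each of ``T = 5`` visits based on
the patient's history, a continuous time-varying confounder ``X_t`` (e.g.
a disease-activity score) affected by past treatment, a continuous
outcome ``Y_t`` (e.g. quality of life), and two time-constant baseline
covariates (a rare binary marker and an age-like continuous covariate).

Causal order within a visit is ``X_t -> A_t -> Y_t``; treatment is decided
from the previous treatment, the current confounder and the most recent
outcome.  Treatment at baseline is structurally zero.  The estimand is the
mean difference in the end-of-follow-up outcome between the "always treat"
and "never treat" regimes (the ATE), which is pinned to a target value by
:func:`calibrate_ate`.

Missingness is imposed afterwards, only at visits ``t >= 1`` and only from
*lagged* quantities (``A_{t-1}, X_{t-1}, Y_{t-1}, B``), so the mechanism
never looks at the values being blanked (missing at random by
construction).  Non-monotone (intermittent) gaps in the outcome and/or the
confounder coexist with monotone drop-out, mirroring the patterns seen in
registry data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

OUTCOME_DISTS = ("normal", "skew_low", "skew_high")
PATTERNS = ("nm_outcome", "nm_confounder", "nm_both", "monotone", "mixed", "none")
LEVELS = ("low", "high")
MISSPECS = ("none", "low", "high")

#: marginal missingness targets (share of person-visits t >= 1), per level,
#: applied separately to the non-monotone and the monotone (drop-out) component
LEVEL_TARGETS = {"low": 0.10, "high": 0.25}

#: log-scale SD of the log-normal outcome noise in the skewed scenarios
SKEW_LOG_SD = {"skew_low": 0.5, "skew_high": 1.0}


class PositivityError(RuntimeError):
    """Empirical treatment probability outside the admissible band."""


class CalibrationError(RuntimeError):
    """A calibration target could not be reached."""


@dataclass(frozen=True)
class DGPCoefficients:
    """All structural coefficients of the generating model.

    Continuous baseline covariate ``B_cont`` is Beta(a, b) rescaled to
    ``[lo, hi]``; it enters every equation standardized by its theoretical
    mean/SD (``b_std``), so slopes are per-SD.  Missingness slopes are on
    the logit of the probability of *being missing* (or of dropping out).
    """

    # baseline covariates
    b_bin_prev: float = 0.06
    b_cont_a: float = 5.0
    b_cont_b: float = 3.0
    b_cont_lo: float = 18.0
    b_cont_hi: float = 90.0
    # time-varying confounder X_t
    x0_sd: float = 1.0
    x_intercept: float = 0.0
    x_on_a_lag: float = -0.2
    x_on_x_lag: float = 0.5
    x_on_b_std: float = 0.3
    x_on_b_bin: float = 0.3
    x_sd: float = 0.866
    # treatment A_t (logistic)
    a_intercept: float = -1.1
    a_on_a_lag: float = 1.8
    a_on_x: float = 0.5
    a_on_y_lag: float = -0.4
    a_on_b_std: float = 0.25
    a_on_b_bin: float = 0.4
    # outcome Y_t
    y_intercept: float = 0.0
    y_on_a: float = 0.04
    y_on_a_lag: float = 0.02
    y_on_x: float = -0.4
    y_on_y_lag: float = 0.0  # autoregressive outcome term, off by default
    y_on_b_std: float = -0.25
    y_on_b_bin: float = -0.3
    y_sigma: float = 1.0
    outcome_dist: str = "normal"
    # confounder-confounder interaction (b_std * x), present only in the
    # misspecification scenarios; analysts' models always omit it
    y_on_bx: float = 0.0
    r_on_bx: float = 0.0
    # missingness / drop-out hazard slopes (shared by both mechanisms)
    m_on_a_lag: float = 0.4
    m_on_x_lag: float = 0.3
    m_on_y_lag: float = -0.3
    m_on_b_std: float = 0.2
    m_on_b_bin: float = 0.3
    # intervention-defined true ATE of this coefficient set
    target_ate: float = 0.2

    def __post_init__(self) -> None:
        if self.outcome_dist not in OUTCOME_DISTS:
            raise ValueError(f"outcome_dist must be one of {OUTCOME_DISTS}")
        if not 0.0 < self.b_bin_prev < 1.0:
            raise ValueError("b_bin_prev must be a probability")
        for name, value in self.__dict__.items():
            if isinstance(value, float) and not math.isfinite(value):
                raise ValueError(f"coefficient {name!r} is not finite")

    # theoretical moments of the rescaled Beta baseline covariate
    @property
    def b_cont_mean(self) -> float:
        a, b = self.b_cont_a, self.b_cont_b
        return self.b_cont_lo + (self.b_cont_hi - self.b_cont_lo) * a / (a + b)

    @property
    def b_cont_sd(self) -> float:
        a, b = self.b_cont_a, self.b_cont_b
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        return (self.b_cont_hi - self.b_cont_lo) * math.sqrt(var)

    def b_std(self, b_cont: np.ndarray) -> np.ndarray:
        return (b_cont - self.b_cont_mean) / self.b_cont_sd


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation factorial."""

    name: str = "scenario"
    pattern: str = "mixed"
    level: str = "high"
    outcome_dist: str = "normal"
    misspec: str = "none"
    n: int = 5000
    n_reps: int = 1000
    m_imputations: int = 50
    base_seed: int = 2023
    n_burnin: int = 5  # chained-equation sweeps per imputation

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}, got {self.pattern!r}")
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.outcome_dist not in OUTCOME_DISTS:
            raise ValueError(f"outcome_dist must be one of {OUTCOME_DISTS}")
        if self.misspec not in MISSPECS:
            raise ValueError(f"misspec must be one of {MISSPECS}")
        if self.n < 1 or self.n_reps < 1 or self.m_imputations < 2:
            raise ValueError("n >= 1, n_reps >= 1 and m_imputations >= 2 required")

    @property
    def nm_target(self) -> float:
        return 0.0 if self.pattern in ("monotone", "none") else LEVEL_TARGETS[self.level]

    @property
    def mono_target(self) -> float:
        return 0.0 if self.pattern == "none" else LEVEL_TARGETS[self.level]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _outcome_noise(coeffs: DGPCoefficients, rng: np.random.Generator, size) -> np.ndarray:
    """Zero-mean outcome noise with SD ``y_sigma``.

    Skewed variants use a shifted log-normal rescaled to unit variance, so
    the linear mean structure (and hence the true ATE) is unchanged while
    the residual distribution is right-skewed.
    """
    if coeffs.outcome_dist == "normal":
        return rng.normal(0.0, coeffs.y_sigma, size)
    sdlog = SKEW_LOG_SD[coeffs.outcome_dist]
    raw = np.exp(rng.normal(0.0, sdlog, size))
    mean = math.exp(sdlog**2 / 2)
    sd = math.sqrt((math.exp(sdlog**2) - 1.0) * math.exp(sdlog**2))
    return coeffs.y_sigma * (raw - mean) / sd


def _check_finite(lp: np.ndarray, equation: str) -> None:
    if not np.all(np.isfinite(lp)):
        raise FloatingPointError(
            f"non-finite linear predictor in the {equation} equation; "
            f"check the {equation!r} coefficients"
        )


from .panel import Panel  # noqa: E402  (import after dataclasses to avoid cycle)


def generate_complete_panel(spec, coeffs: DGPCoefficients, seed, T: int = 5) -> Panel:
    """Draw a fully observed cohort under the sequential structural model.

    ``spec`` may be a :class:`ScenarioSpec` or an integer sample size.
    The empirical treatment prevalence must stay strictly inside
    ``(0.05, 0.95)`` at every post-baseline visit (positivity check).
    """
    n = spec.n if isinstance(spec, ScenarioSpec) else int(spec)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _as_rng(seed)

    b_bin = (rng.random(n) < coeffs.b_bin_prev).astype(int)
    b_cont = coeffs.b_cont_lo + (coeffs.b_cont_hi - coeffs.b_cont_lo) * rng.beta(
        coeffs.b_cont_a, coeffs.b_cont_b, n
    )
    bs = coeffs.b_std(b_cont)
    bb = b_bin.astype(float)

    x = np.empty((n, T))
    a = np.zeros((n, T), dtype=int)
    y = np.empty((n, T))
    eps_y = _outcome_noise(coeffs, rng, (n, T))

    for t in range(T):
        if t == 0:
            lp_x = coeffs.x_intercept + coeffs.x_on_b_std * bs + coeffs.x_on_b_bin * bb
            _check_finite(lp_x, "confounder")
            x[:, 0] = lp_x + rng.normal(0.0, coeffs.x0_sd, n)
            # A_0 structurally zero
        else:
            lp_x = (
                coeffs.x_intercept
                + coeffs.x_on_a_lag * a[:, t - 1]
                + coeffs.x_on_x_lag * x[:, t - 1]
                + coeffs.x_on_b_std * bs
                + coeffs.x_on_b_bin * bb
            )
            _check_finite(lp_x, "confounder")
            x[:, t] = lp_x + rng.normal(0.0, coeffs.x_sd, n)
            lp_a = (
                coeffs.a_intercept
                + coeffs.a_on_a_lag * a[:, t - 1]
                + coeffs.a_on_x * x[:, t]
                + coeffs.a_on_y_lag * y[:, t - 1]
                + coeffs.a_on_b_std * bs
                + coeffs.a_on_b_bin * bb
            )
            _check_finite(lp_a, "treatment")
            a[:, t] = rng.random(n) < expit(lp_a)
        a_lag = a[:, t - 1] if t > 0 else np.zeros(n)
        y_lag = y[:, t - 1] if t > 0 else np.zeros(n)
        lp_y = (
            coeffs.y_intercept
            + coeffs.y_on_a * a[:, t]
            + coeffs.y_on_a_lag * a_lag
            + coeffs.y_on_x * x[:, t]
            + coeffs.y_on_y_lag * y_lag
            + coeffs.y_on_b_std * bs
            + coeffs.y_on_b_bin * bb
            + coeffs.y_on_bx * bs * x[:, t]
        )
        _check_finite(lp_y, "outcome")
        y[:, t] = lp_y + eps_y[:, t]

    prev = a[:, 1:].mean(axis=0)
    if np.any(prev <= 0.05) or np.any(prev >= 0.95):
        raise PositivityError(
            f"empirical treatment prevalence per visit {np.round(prev, 3)} "
            "outside (0.05, 0.95)"
        )

    ones = np.ones((n, T), dtype=int)
    return Panel(
        b_bin=b_bin, b_cont=b_cont, x=x, a=a, y=y,
        r_x=ones.copy(), r_y=ones.copy(), c=np.zeros((n, T), dtype=int),
    )


# ----------------------------------------------------------------------
# true-ATE oracle and effect calibration
# ----------------------------------------------------------------------

def _simulate_forced(coeffs: DGPCoefficients, a_value: int, b_std, b_bin,
                     eps_x0, eps_x, eps_y, T: int) -> np.ndarray:
    """End-of-follow-up outcome under a static regime, with supplied noise."""
    n = b_std.shape[0]
    bs, bb = b_std, b_bin
    x_prev = coeffs.x_intercept + coeffs.x_on_b_std * bs + coeffs.x_on_b_bin * bb + eps_x0
    a_prev = np.zeros(n)
    y_prev = (
        coeffs.y_intercept + coeffs.y_on_x * x_prev + coeffs.y_on_b_std * bs
        + coeffs.y_on_b_bin * bb + coeffs.y_on_bx * bs * x_prev + eps_y[:, 0]
    )
    for t in range(1, T):
        x_t = (
            coeffs.x_intercept + coeffs.x_on_a_lag * a_prev + coeffs.x_on_x_lag * x_prev
            + coeffs.x_on_b_std * bs + coeffs.x_on_b_bin * bb + eps_x[:, t - 1]
        )
        a_t = np.full(n, float(a_value))
        y_t = (
            coeffs.y_intercept + coeffs.y_on_a * a_t + coeffs.y_on_a_lag * a_prev
            + coeffs.y_on_x * x_t + coeffs.y_on_y_lag * y_prev
            + coeffs.y_on_b_std * bs + coeffs.y_on_b_bin * bb
            + coeffs.y_on_bx * bs * x_t + eps_y[:, t]
        )
        x_prev, a_prev, y_prev = x_t, a_t, y_t
    return y_prev


def true_ate_oracle(coeffs: DGPCoefficients, n_large: int = 1_000_000,
                    seed=0, T: int = 5) -> float:
    """True ATE by intervention: always-treat minus never-treat.

    Both counterfactual arms are simulated with common random numbers, so
    for the (additive-noise) structural model the per-person contrast is
    noise-free and the Monte Carlo error is essentially nil.
    """
    rng = _as_rng(seed)
    b_bin = (rng.random(n_large) < coeffs.b_bin_prev).astype(float)
    b_cont = coeffs.b_cont_lo + (coeffs.b_cont_hi - coeffs.b_cont_lo) * rng.beta(
        coeffs.b_cont_a, coeffs.b_cont_b, n_large
    )
    bs = coeffs.b_std(b_cont)
    eps_x0 = rng.normal(0.0, coeffs.x0_sd, n_large)
    eps_x = rng.normal(0.0, coeffs.x_sd, (n_large, T - 1))
    eps_y = _outcome_noise(coeffs, rng, (n_large, T))
    y_always = _simulate_forced(coeffs, 1, bs, b_bin, eps_x0, eps_x, eps_y, T)
    y_never = _simulate_forced(coeffs, 0, bs, b_bin, eps_x0, eps_x, eps_y, T)
    return float(np.mean(y_always - y_never))


def _scale_effects(coeffs: DGPCoefficients, s: float) -> DGPCoefficients:
    return replace(
        coeffs,
        y_on_a=coeffs.y_on_a * s,
        y_on_a_lag=coeffs.y_on_a_lag * s,
        x_on_a_lag=coeffs.x_on_a_lag * s,
    )


def calibrate_ate(coeffs: DGPCoefficients, target: float, n_large: int = 200_000,
                  seed=0, tol: float = 0.002) -> DGPCoefficients:
    """Rescale treatment-effect coefficients so the true ATE equals ``target``.

    A common multiplier is applied to the direct (``y_on_a``, ``y_on_a_lag``)
    and mediated (``x_on_a_lag``) effect paths; the ATE is linear in that
    multiplier, so a single oracle evaluation determines it, and a
    bracketed root search is used as a safety net.
    """
    if not math.isfinite(target):
        raise ValueError("target ATE must be finite")
    if target == 0.0:
        return replace(_scale_effects(coeffs, 0.0), target_ate=0.0)
    ate_unit = true_ate_oracle(coeffs, n_large, seed)
    if abs(ate_unit) < 1e-12:
        raise CalibrationError(
            "treatment-effect coefficients are all zero; no multiplier can "
            f"reach target ATE {target}"
        )
    s = target / ate_unit
    out = replace(_scale_effects(coeffs, s), target_ate=float(target))
    achieved = true_ate_oracle(out, n_large, seed)
    if abs(achieved - target) > tol:
        f = lambda m: true_ate_oracle(_scale_effects(coeffs, m), n_large, seed) - target
        lo, hi = (0.0, 2 * s) if s > 0 else (2 * s, 0.0)
        if f(lo) * f(hi) > 0:
            raise CalibrationError("no sign-compatible effect multiplier found")
        s = brentq(f, lo, hi, xtol=1e-6)
        out = replace(_scale_effects(coeffs, s), target_ate=float(target))
    return out


# ----------------------------------------------------------------------
# missingness imposition
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class MissingnessDesign:
    """Calibrated intercepts for one (pattern, level) missingness cell."""

    pattern: str
    level: str
    nm_intercept: Optional[float]
    dropout_intercept: Optional[float]
    nm_target: float = 0.0
    mono_target: float = 0.0


def _missing_lps(coeffs: DGPCoefficients, panel: Panel) -> np.ndarray:
    """(n, T-1) slope part of the missingness logit at visits 1..T-1.

    Predictors are exclusively lagged: the mechanism never uses the
    current-visit values it may blank.
    """
    bs = coeffs.b_std(panel.b_cont)
    bb = panel.b_bin.astype(float)
    a_lag = panel.a[:, :-1]
    x_lag = panel.x[:, :-1]
    y_lag = panel.y[:, :-1]
    lp = (
        coeffs.m_on_a_lag * a_lag
        + coeffs.m_on_x_lag * x_lag
        + coeffs.m_on_y_lag * y_lag
        + (coeffs.m_on_b_std * bs + coeffs.m_on_b_bin * bb)[:, None]
        + coeffs.r_on_bx * (bs[:, None] * x_lag)
    )
    _check_finite(lp, "missingness")
    return lp


_DESIGN_CACHE: dict = {}
_CALIBRATION_SEED = 20230919  # fixed: calibration is part of the shipped design
_CALIBRATION_N = 40_000


def calibrate_missingness_intercepts(
    spec: ScenarioSpec,
    coeffs: DGPCoefficients,
    n_cal: int = _CALIBRATION_N,
    seed: int = _CALIBRATION_SEED,
    tol: float = 0.005,
) -> MissingnessDesign:
    """Solve for missingness-model intercepts hitting the marginal targets.

    The expected marginal proportions (over person-visits ``t >= 1``) are
    computed analytically on a large fixed calibration cohort — drop-out
    via the discrete-hazard survival product, intermittent gaps via the
    per-visit blanking probability among not-yet-dropped visits — and each
    intercept is found by bracketed root search on ``[-20, 20]``.
    Results are cached per (pattern, level, coefficients).
    """
    key = (spec.pattern, spec.level, coeffs, n_cal, seed)
    if key in _DESIGN_CACHE:
        return _DESIGN_CACHE[key]

    if spec.pattern == "none":
        design = MissingnessDesign(spec.pattern, spec.level, None, None)
        _DESIGN_CACHE[key] = design
        return design

    panel = generate_complete_panel(n_cal, coeffs, seed)
    lps = _missing_lps(coeffs, panel)

    def mono_frac(c0: float) -> float:
        h = expit(c0 + lps)
        surv = np.cumprod(1.0 - h, axis=1)
        return float(np.mean(1.0 - surv))

    lo, hi = -20.0, 20.0
    target = spec.mono_target
    if not mono_frac(lo) <= target <= mono_frac(hi):
        raise CalibrationError(
            f"monotone target {target} unreachable for intercepts in [{lo}, {hi}]"
        )
    c0 = brentq(lambda v: mono_frac(v) - target, lo, hi, xtol=1e-8)
    if abs(mono_frac(c0) - target) > tol:
        raise CalibrationError("drop-out intercept calibration failed")

    nm0 = None
    if spec.nm_target > 0:
        h = expit(c0 + lps)
        surv = np.cumprod(1.0 - h, axis=1)  # P(not yet dropped at t)

        def nm_frac(b0: float) -> float:
            p = expit(b0 + lps)
            p_any = 1.0 - (1.0 - p) ** 2 if spec.pattern == "mixed" else p
            return float(np.mean(surv * p_any))

        if not nm_frac(lo) <= spec.nm_target <= nm_frac(hi):
            raise CalibrationError(
                f"non-monotone target {spec.nm_target} unreachable in [{lo}, {hi}]"
            )
        nm0 = brentq(lambda v: nm_frac(v) - spec.nm_target, lo, hi, xtol=1e-8)
        if abs(nm_frac(nm0) - spec.nm_target) > tol:
            raise CalibrationError("non-monotone intercept calibration failed")

    design = MissingnessDesign(
        spec.pattern, spec.level, nm0, c0,
        nm_target=spec.nm_target, mono_target=spec.mono_target,
    )
    _DESIGN_CACHE[key] = design
    return design


def impose_missingness(
    panel: Panel,
    spec: ScenarioSpec,
    coeffs: DGPCoefficients,
    seed,
    design: Optional[MissingnessDesign] = None,
) -> Panel:
    """Blank cells of a complete panel under the scenario's MAR patterns.

    Baseline (t = 0) is never blanked and treatment is always recorded.
    Drop-out is absorbing and blanks both x and y; the non-monotone
    component blanks the pattern's variables at not-yet-dropped visits.
    """
    if not panel.is_complete():
        raise ValueError("impose_missingness expects a complete panel")
    if spec.pattern == "none":
        return panel.copy()
    if design is None:
        design = calibrate_missingness_intercepts(spec, coeffs)
    rng = _as_rng(seed)
    out = panel.copy()
    n, T = panel.n, panel.T
    lps = _missing_lps(coeffs, panel)

    # monotone drop-out (absorbing)
    h = expit(design.dropout_intercept + lps)
    dropped = np.cumsum(rng.random((n, T - 1)) < h, axis=1) > 0
    out.c[:, 1:] = dropped.astype(int)

    miss_x = dropped.copy()
    miss_y = dropped.copy()
    if design.nm_intercept is not None:
        p = expit(design.nm_intercept + lps)
        keep = ~dropped
        if spec.pattern == "nm_outcome":
            miss_y |= (rng.random((n, T - 1)) < p) & keep
        elif spec.pattern == "nm_confounder":
            miss_x |= (rng.random((n, T - 1)) < p) & keep
        elif spec.pattern == "nm_both":
            joint = (rng.random((n, T - 1)) < p) & keep
            miss_x |= joint
            miss_y |= joint
        elif spec.pattern == "mixed":
            miss_y |= (rng.random((n, T - 1)) < p) & keep
            miss_x |= (rng.random((n, T - 1)) < p) & keep
        else:  # pragma: no cover - guarded by ScenarioSpec validation
            raise ValueError(f"unknown pattern {spec.pattern!r}")

    out.r_x[:, 1:] = (~miss_x).astype(int)
    out.r_y[:, 1:] = (~miss_y).astype(int)
    out.x[:, 1:][miss_x] = np.nan
    out.y[:, 1:][miss_y] = np.nan
    return out


def missingness_summary(panel: Panel) -> dict:
    """Realized marginal proportions over person-visits ``t >= 1``."""
    dropped = panel.c[:, 1:] == 1
    nm = ((panel.r_x[:, 1:] == 0) | (panel.r_y[:, 1:] == 0)) & ~dropped
    return {
        "nonmonotone": float(nm.mean()),
        "monotone": float(dropped.mean()),
        "any": float((nm | dropped).mean()),
    }
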