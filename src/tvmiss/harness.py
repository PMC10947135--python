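"""Factorial simulation harness and performance measures.

Each replication draws one complete cohort, imposes the scenario's
missingness, and hands the *same* incomplete data to every method:

* ``complete_data_reference`` — stabilized-weight MSM on the cohort before
  any blanking; guards the generator/estimator pair.
* ``IPW`` — censor after the first missing observation, estimate
  missingness and treatment models, weight the remaining complete cases
  by the total (treatment x missingness) stabilized weight.
* ``MI_linear`` / ``MI_PMM`` — chained-equation imputation, then a
  stabilized-weight MSM inside each completed dataset, pooled by
  Rubin's rules (weights are re-estimated per imputation, never pooled).

Performance per scenario x method: mean estimate, bias, empirical SE and
rMSE, each with its Monte Carlo standard error.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, replace
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import config as _config
from .dgp import (
    DGPCoefficients,
    MissingnessDesign,
    ScenarioSpec,
    calibrate_missingness_intercepts,
    generate_complete_panel,
    impose_missingness,
)
from .mice import default_method_map, mice_run, rubin_combine
from .msm import ate_always_vs_never, fit_msm
from .panel import Panel
from .weights import (
    censor_after_first_missing,
    fit_missingness_models,
    fit_treatment_models,
    stabilized_missingness_weights,
    stabilized_treatment_weights,
    total_weights,
)

METHODS = ("complete_data_reference", "IPW", "MI_linear", "MI_PMM")


@dataclass
class ReplicationRecord:
    scenario: str
    rep: int
    method: str
    estimate: float
    se: float
    seed: int
    runtime: float
    error: str = ""


# ----------------------------------------------------------------------
# single-dataset pipelines
# ----------------------------------------------------------------------

def sw_msm_estimate(panel: Panel):
    """Stabilized-treatment-weight MSM on complete (or completed) data."""
    models = fit_treatment_models(panel)
    sw = stabilized_treatment_weights(panel, models)
    fit = fit_msm(panel, sw)
    return ate_always_vs_never(fit)


def ipw_estimate(panel: Panel):
    """Censor-after-first-missing IPW: total-weight MSM on complete cases."""
    cens = censor_after_first_missing(panel)
    obs = cens.observed()
    m_models = fit_missingness_models(cens)
    mw = stabilized_missingness_weights(cens, m_models)
    t_models = fit_treatment_models(cens, observed=obs)
    sw = stabilized_treatment_weights(cens, t_models, observed=obs)
    tw = total_weights(sw, mw)
    fit = fit_msm(cens, tw)
    return ate_always_vs_never(fit)


def mi_estimate(panel: Panel, M: int, n_iter: int, seed, pmm: bool = False, q: int = 5):
    """MI then per-imputation SW-MSM, pooled by Rubin's rules."""
    method_map = default_method_map(panel, pmm_for_outcome=pmm)
    stack = mice_run(panel, M=M, n_iter=n_iter, method_map=method_map, q=q, seed=seed)
    per_imp = []
    for completed in stack.panels:
        est, se = sw_msm_estimate(completed)
        per_imp.append((est, se**2))
    pooled = rubin_combine(per_imp)
    return pooled.theta, pooled.se


# ----------------------------------------------------------------------
# replications and scenarios
# ----------------------------------------------------------------------

def _default_methods(spec: ScenarioSpec) -> List[str]:
    methods = ["complete_data_reference", "IPW", "MI_linear"]
    if spec.outcome_dist != "normal":
        methods.append("MI_PMM")
    return methods


def run_replication(
    spec: ScenarioSpec,
    rep_index: int,
    coeffs: Optional[DGPCoefficients] = None,
    design: Optional[MissingnessDesign] = None,
    methods: Optional[Sequence[str]] = None,
) -> List[ReplicationRecord]:
    """Run every requested method once on a freshly simulated dataset."""
    if coeffs is None:
        coeffs = _config.default_coefficients(spec.outcome_dist, spec.misspec)
    if methods is None:
        methods = _default_methods(spec)
    bad = set(methods) - set(METHODS)
    if bad:
        raise ValueError(f"unknown methods {sorted(bad)}; choose from {METHODS}")
    if design is None and spec.pattern != "none":
        design = calibrate_missingness_intercepts(spec, coeffs)

    ss = np.random.SeedSequence(spec.base_seed, spawn_key=(rep_index,))
    s_gen, s_miss, s_mi_lin, s_mi_pmm = ss.spawn(4)
    seed_id = int(ss.generate_state(1)[0] % (2**31))

    panel = generate_complete_panel(spec.n, coeffs, np.random.default_rng(s_gen))
    if spec.pattern == "none":
        mpanel = panel
    else:
        mpanel = impose_missingness(panel, spec, coeffs, np.random.default_rng(s_miss),
                                    design)

    records = []

    def run(method, fn):
        t0 = time.perf_counter()
        try:
            est, se = fn()
            err = ""
        except Exception as exc:  # record-and-continue failure policy
            est, se, err = np.nan, np.nan, f"{type(exc).__name__}: {exc}"
        records.append(ReplicationRecord(
            scenario=spec.name, rep=rep_index, method=method,
            estimate=est, se=se, seed=seed_id,
            runtime=time.perf_counter() - t0, error=err,
        ))

    for method in methods:
        if method == "complete_data_reference":
            run(method, lambda: sw_msm_estimate(panel))
        elif method == "IPW":
            run(method, lambda: ipw_estimate(mpanel))
        elif method == "MI_linear":
            run(method, lambda: mi_estimate(
                mpanel, spec.m_imputations, spec.n_burnin, s_mi_lin, pmm=False))
        elif method == "MI_PMM":
            run(method, lambda: mi_estimate(
                mpanel, spec.m_imputations, spec.n_burnin, s_mi_pmm, pmm=True))
    return records


def run_scenario(
    spec: ScenarioSpec,
    coeffs: Optional[DGPCoefficients] = None,
    methods: Optional[Sequence[str]] = None,
    max_failure_rate: float = 0.05,
) -> "ScenarioResult":
    """Execute all replications of one scenario and aggregate performance."""
    if spec.n_reps < 2:
        raise ValueError("need at least 2 replications to estimate empirical SE")
    if coeffs is None:
        coeffs = _config.default_coefficients(spec.outcome_dist, spec.misspec)
    design = (calibrate_missingness_intercepts(spec, coeffs)
              if spec.pattern != "none" else None)
    all_records: List[ReplicationRecord] = []
    for rep in range(spec.n_reps):
        all_records.extend(run_replication(spec, rep, coeffs, design, methods))
    records = pd.DataFrame([asdict(r) for r in all_records])
    table = performance_table(records, theta=coeffs.target_ate)
    table.insert(0, "scenario", spec.name)
    failure = records.groupby("method")["error"].apply(lambda e: (e != "").mean())
    table["failure_rate"] = table["method"].map(failure)
    table["valid"] = table["failure_rate"] <= max_failure_rate
    return ScenarioResult(spec=spec, records=records, performance=table,
                          theta=coeffs.target_ate)


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    records: pd.DataFrame
    performance: pd.DataFrame
    theta: float


def performance_table(records: pd.DataFrame, theta: float) -> pd.DataFrame:
    """Bias / empirical SE / rMSE per method, with Monte Carlo SEs.

    ``rmse**2 == bias**2 + emp_se**2 * (R-1)/R`` holds exactly per row.
    """
    rows = []
    for method, grp in records.groupby("method", sort=False):
        est = grp.loc[grp["error"] == "", "estimate"].to_numpy()
        est = est[np.isfinite(est)]
        R = est.size
        if R < 2:
            rows.append({"method": method, "n_reps": R, "mean_est": np.nan,
                         "bias": np.nan, "emp_se": np.nan, "rmse": np.nan,
                         "mcse_bias": np.nan, "mcse_emp_se": np.nan,
                         "mcse_rmse": np.nan})
            continue
        errors = est - theta
        bias = errors.mean()
        emp_se = est.std(ddof=1)
        sq = errors**2
        rmse = float(np.sqrt(sq.mean()))
        mcse_bias = emp_se / np.sqrt(R)
        mcse_emp_se = emp_se / np.sqrt(2.0 * (R - 1))
        mcse_rmse = (np.sqrt(sq.var(ddof=1) / R) / (2.0 * rmse)) if rmse > 0 else 0.0
        rows.append({
            "method": method, "n_reps": R, "mean_est": est.mean(), "bias": bias,
            "emp_se": emp_se, "rmse": rmse, "mcse_bias": mcse_bias,
            "mcse_emp_se": mcse_emp_se, "mcse_rmse": mcse_rmse,
        })
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# the factorial grid
# ----------------------------------------------------------------------

NM_PATTERNS = ("nm_outcome", "nm_confounder", "nm_both", "monotone")


def scenario_grid(
    full_scale: bool = True,
    reduced_twins: bool = True,
    base_seed: int = 2023,
) -> List[ScenarioSpec]:
    """The study's factorial: normal-outcome cells (plus reduced-scale
    twins at n = 1000), skewed-outcome cells and misspecification cells."""
    grid: List[ScenarioSpec] = []
    seed = base_seed

    def add(**kw):
        nonlocal seed
        grid.append(ScenarioSpec(base_seed=seed, **kw))
        seed += 1

    sizes = []
    if full_scale:
        sizes.append((5000, 1000, 50, ""))
    if reduced_twins:
        sizes.append((1000, 1000, 50, "_n1000"))
    for n, reps, m, suffix in sizes:
        for pattern in NM_PATTERNS + ("mixed",):
            for level in ("low", "high"):
                add(name=f"normal_{pattern}_{level}{suffix}", pattern=pattern,
                    level=level, outcome_dist="normal", n=n, n_reps=reps,
                    m_imputations=m)
    n, reps, m = (5000, 1000, 50) if full_scale else (1000, 1000, 50)
    for dist in ("skew_low", "skew_high"):
        for level in ("low", "high"):
            add(name=f"{dist}_mixed_{level}", pattern="mixed", level=level,
                outcome_dist=dist, n=n, n_reps=reps, m_imputations=m)
    for misspec in ("low", "high"):
        add(name=f"misspec_{misspec}_mixed_high", pattern="mixed", level="high",
            outcome_dist="normal", misspec=misspec, n=n, n_reps=reps,
            m_imputations=m)
    return grid


def reduced_scale(spec: ScenarioSpec, n: int = 1000, n_reps: int = 200,
                  m_imputations: int = 10) -> ScenarioSpec:
    """Reduced-scale twin of a scenario (desk-scale reproduction runs)."""
    return replace(spec, name=spec.name + "_reduced", n=n, n_reps=n_reps,
                   m_imputations=m_imputations)
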