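"""Stabilized inverse-probability weights for treatment and missingness.

Pooled logistic models (all post-baseline visits stacked, with visit
indicator terms) provide the visit-level probabilities; weights are
cumulative products of stabilized visit ratios.  Treatment weights break
the confounder -> treatment arrows; missingness weights re-weight complete
cases for informative censoring, with the panel first *monotonized*
(censored after the first missing observation) so a single discrete-hazard
observation process remains.

The baseline visit contributes ratio 1 to every cumulative weight:
treatment at t = 0 is structurally zero and baseline data are complete.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

from ._glm import DegenerateResponseError, SeparationError, fit_logit
from .panel import Panel


class PositivityViolation(RuntimeError):
    """All-one or all-zero treatment (or observation) at some visit."""


@dataclass
class PooledLogit:
    """A fitted pooled logistic model: named columns, coefficients, covariance."""

    columns: list
    beta: np.ndarray
    cov: np.ndarray
    n_rows: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, dtype=float) @ self.beta)

    def summary_dict(self) -> dict:
        se = np.sqrt(np.diag(self.cov))
        return {
            "columns": list(self.columns),
            "beta": [float(b) for b in self.beta],
            "se": [float(s) for s in se],
            "n_rows": int(self.n_rows),
        }


@dataclass
class ConstantModel:
    """Degenerate probability model (used when every unit is observed)."""

    p: float = 1.0
    columns: list = field(default_factory=list)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(np.asarray(X).shape[0], self.p)

    def summary_dict(self) -> dict:
        return {"constant": self.p}


@dataclass
class WeightVector:
    """Per (person, visit) stabilized weight components.

    ``num``/``den`` hold the visit-level numerator and denominator
    probabilities of the realized treatment (or of remaining observed);
    visit 0 carries 1.  ``cumulative`` is the running product of
    ``num/den``; entries after a person's support end are NaN.
    """

    kind: str
    num: np.ndarray  # (n, T)
    den: np.ndarray  # (n, T)

    def __post_init__(self) -> None:
        if self.num.shape != self.den.shape:
            raise ValueError("numerator/denominator probability shapes differ")
        for name in ("num", "den"):
            arr = getattr(self, name)
            bad = (~np.isnan(arr)) & ((arr <= 0) | (arr >= 1)) & (arr != 1.0)
            if np.any(bad):
                raise ValueError(f"{name} probabilities must lie in (0, 1]")

    @property
    def ratio(self) -> np.ndarray:
        return self.num / self.den

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumprod(self.ratio, axis=1)

    def final(self) -> np.ndarray:
        """Cumulative weight at the end of follow-up."""
        return self.cumulative[:, -1]

    def to_frame(self):
        import pandas as pd

        n, T = self.num.shape
        return pd.DataFrame({
            "id": np.repeat(np.arange(n), T),
            "t": np.tile(np.arange(T), n),
            "kind": self.kind,
            "num": self.num.ravel(),
            "den": self.den.ravel(),
            "ratio": self.ratio.ravel(),
            "cumulative": self.cumulative.ravel(),
        })


def _visit_dummies(t_idx: np.ndarray, T: int) -> np.ndarray:
    # visits 1..T-1 pooled; dummies for t >= 2 (t = 1 is the reference)
    return np.column_stack([(t_idx == t).astype(float) for t in range(2, T)])


def _stack_rows(panel: Panel, mask: np.ndarray, lagged_only: bool):
    """Stack person-visit rows t >= 1 selected by ``mask`` (n, T)."""
    n, T = panel.n, panel.T
    rows_i, rows_t = np.nonzero(mask[:, 1:])
    rows_t = rows_t + 1
    a_lag = panel.a[rows_i, rows_t - 1].astype(float)
    b_cont = panel.b_cont[rows_i]
    b_bin = panel.b_bin[rows_i].astype(float)
    dummies = _visit_dummies(rows_t, T)
    num_X = np.column_stack([np.ones(rows_i.size), dummies, a_lag, b_cont, b_bin])
    num_cols = ["const"] + [f"visit_{t}" for t in range(2, T)] + ["a_lag", "b_cont", "b_bin"]
    if lagged_only:
        x_lag = panel.x[rows_i, rows_t - 1]
        y_lag = panel.y[rows_i, rows_t - 1]
        den_X = np.column_stack([num_X, x_lag, y_lag])
        den_cols = num_cols + ["x_lag", "y_lag"]
    else:
        x_cur = panel.x[rows_i, rows_t]
        y_lag = panel.y[rows_i, rows_t - 1]
        den_X = np.column_stack([num_X, x_cur, y_lag])
        den_cols = num_cols + ["x_cur", "y_lag"]
    return rows_i, rows_t, num_X, num_cols, den_X, den_cols


# ----------------------------------------------------------------------
# treatment models
# ----------------------------------------------------------------------

def fit_treatment_models(panel: Panel, observed: Optional[np.ndarray] = None):
    """Pooled logistic models for treatment receipt at visits ``t >= 1``.

    Denominator: ``A_t ~ visit + A_{t-1} + X_t + Y_{t-1} + B``;
    numerator: ``A_t ~ visit + A_{t-1} + B`` (history-restricted, for
    stabilization).  ``observed`` restricts the fitting rows (IPW path
    after monotonization); by default all person-visits are used, which
    requires a complete or completed panel.
    """
    if observed is None:
        observed = np.ones((panel.n, panel.T), dtype=bool)
    rows_i, rows_t, num_X, num_cols, den_X, den_cols = _stack_rows(panel, observed, False)
    if np.isnan(den_X).any():
        i, j = np.argwhere(np.isnan(den_X))[0]
        raise ValueError(
            f"missing covariate {den_cols[j]!r} at person {rows_i[i]}, visit {rows_t[i]}; "
            "impute or censor before fitting treatment models"
        )
    y = panel.a[rows_i, rows_t].astype(float)
    for t in range(1, panel.T):
        at = y[rows_t == t]
        if at.size and (at.min() == at.max()):
            raise PositivityViolation(f"treatment is constant ({int(at[0])}) at visit {t}")
    try:
        beta_n, cov_n = fit_logit(num_X, y)
        beta_d, cov_d = fit_logit(den_X, y)
    except (SeparationError, DegenerateResponseError) as exc:
        raise SeparationError(f"treatment model could not be fitted: {exc}") from exc
    num = PooledLogit(num_cols, beta_n, cov_n, y.size)
    den = PooledLogit(den_cols, beta_d, cov_d, y.size)
    return num, den


def stabilized_treatment_weights(
    panel: Panel, models, observed: Optional[np.ndarray] = None
) -> WeightVector:
    """Cumulative stabilized treatment weights SW_t for every person."""
    num_model, den_model = models
    if observed is None:
        observed = np.ones((panel.n, panel.T), dtype=bool)
    rows_i, rows_t, num_X, _, den_X, _ = _stack_rows(panel, observed, False)
    a_real = panel.a[rows_i, rows_t].astype(float)
    p_num = num_model.predict(num_X)
    p_den = den_model.predict(den_X)
    # probability of the *realized* treatment
    pr_num = np.where(a_real == 1, p_num, 1.0 - p_num)
    pr_den = np.where(a_real == 1, p_den, 1.0 - p_den)
    n, T = panel.n, panel.T
    num = np.full((n, T), np.nan)
    den = np.full((n, T), np.nan)
    num[:, 0] = den[:, 0] = 1.0  # baseline: A_0 deterministic
    num[rows_i, rows_t] = pr_num
    den[rows_i, rows_t] = pr_den
    return WeightVector("treatment", num, den)


# ----------------------------------------------------------------------
# monotonization and missingness models
# ----------------------------------------------------------------------

def censor_after_first_missing(panel: Panel) -> Panel:
    """Censor each person at their first visit with any unobserved cell.

    The first missing visit itself and everything after become fully
    unobserved; earlier visits are untouched.  The result has monotone
    missingness for every person, whatever the original pattern.
    """
    out = panel.copy()
    any_missing = (panel.r_x == 0) | (panel.r_y == 0)
    censored = np.cumsum(any_missing, axis=1) > 0
    out.r_x[censored] = 0
    out.r_y[censored] = 0
    out.x[censored] = np.nan
    out.y[censored] = np.nan
    return out


def fit_missingness_models(panel: Panel):
    """Discrete-hazard models for remaining observed, on a monotonized panel.

    For each visit ``t >= 1``, among persons observed at ``t-1``, the
    binary outcome is "fully observed at t".  Denominator conditions on
    ``A_{t-1}, X_{t-1}, Y_{t-1}, B`` (plus visit terms); the numerator on
    ``A_{t-1}, B`` only.  If nobody is ever missing both models collapse
    to constant probability one.
    """
    if not panel.is_monotone():
        raise ValueError("fit_missingness_models expects a monotonized panel "
                         "(apply censor_after_first_missing first)")
    obs = panel.observed()
    at_risk = np.ones((panel.n, panel.T), dtype=bool)
    at_risk[:, 1:] = obs[:, :-1]  # observed at t-1 (baseline always observed)
    rows_i, rows_t, num_X, num_cols, den_X, den_cols = _stack_rows(panel, at_risk, True)
    y = obs[rows_i, rows_t].astype(float)
    if y.min() == y.max():
        if y.min() == 1.0:
            return ConstantModel(1.0), ConstantModel(1.0)
        raise PositivityViolation("no person remains observed after baseline")
    try:
        beta_n, cov_n = fit_logit(num_X, y)
        beta_d, cov_d = fit_logit(den_X, y)
    except (SeparationError, DegenerateResponseError) as exc:
        raise SeparationError(f"missingness model could not be fitted: {exc}") from exc
    return (PooledLogit(num_cols, beta_n, cov_n, y.size),
            PooledLogit(den_cols, beta_d, cov_d, y.size))


def stabilized_missingness_weights(panel: Panel, models) -> WeightVector:
    """Cumulative stabilized weights for remaining observed (IPMW)."""
    num_model, den_model = models
    obs = panel.observed()
    at_risk = np.ones((panel.n, panel.T), dtype=bool)
    at_risk[:, 1:] = obs[:, :-1]
    rows_i, rows_t, num_X, _, den_X, _ = _stack_rows(panel, at_risk, True)
    p_num = num_model.predict(num_X)
    p_den = den_model.predict(den_X)
    n, T = panel.n, panel.T
    num = np.full((n, T), np.nan)
    den = np.full((n, T), np.nan)
    num[:, 0] = den[:, 0] = 1.0  # baseline fully observed
    # the weight contribution is the probability of being observed; it is
    # only consumed along visits where the person *is* observed
    keep = obs[rows_i, rows_t]
    num[rows_i[keep], rows_t[keep]] = p_num[keep]
    den[rows_i[keep], rows_t[keep]] = p_den[keep]
    return WeightVector("missingness", num, den)


def total_weights(*components: WeightVector) -> WeightVector:
    """Elementwise product of stabilized weight components (SW x IPMW ...)."""
    if not components:
        raise ValueError("at least one weight component required")
    shape = components[0].num.shape
    for w in components:
        if w.num.shape != shape:
            raise ValueError("weight components are on different (id, t) supports")
    num = components[0].num.copy()
    den = components[0].den.copy()
    for w in components[1:]:
        num *= w.num
        den *= w.den
    return WeightVector("total", num, den)


def export_model_summaries(path, **models) -> None:
    """Write fitted weight-model summaries as JSON."""
    payload = {name: m.summary_dict() for name, m in models.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
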