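"""Weighted marginal structural model for the end-of-follow-up outcome.

The MSM is ``E[Y_{T-1}^{a}] = alpha + sum_{t>=1} beta_t a_t``: weighted
least squares of the final outcome on the treatment history, using each
person's cumulative stabilized (or total) weight at the final visit.
Treatment at baseline is structurally zero, so it carries no coefficient.
The always-vs-never ATE is the sum of the per-visit coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import statsmodels.api as sm

from .panel import Panel
from .weights import WeightVector


@dataclass
class MSMFit:
    alpha: float
    beta: np.ndarray            # per-visit treatment coefficients, t = 1..T-1
    cov: np.ndarray             # robust covariance of (alpha, beta)
    weight_kind: str
    n_ids: int
    weight_stats: dict

    @property
    def beta_cov(self) -> np.ndarray:
        return self.cov[1:, 1:]

    def to_json(self, path=None) -> str:
        payload = {
            "alpha": self.alpha,
            "beta": [float(b) for b in self.beta],
            "cov": self.cov.tolist(),
            "weight_kind": self.weight_kind,
            "n_ids": self.n_ids,
            "weight_stats": self.weight_stats,
            "ate": ate_always_vs_never(self)[0],
            "ate_se": ate_always_vs_never(self)[1],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def fit_msm(panel: Panel, weights, weight_kind: Optional[str] = None,
            adjust_baseline: bool = True) -> MSMFit:
    """Weighted least squares of ``Y_{T-1}`` on ``(A_1, ..., A_{T-1})``.

    ``weights`` is a :class:`WeightVector` (its final cumulative weight is
    used) or an array of per-person weights; persons with NaN weight or
    unobserved final outcome are dropped (the IPW complete-case path).
    Coefficient covariance is the HC0 sandwich.

    Because the stabilized-weight numerators condition on the baseline
    covariates ``B``, the outcome model must adjust for them as well
    (``adjust_baseline``, on by default): in the reweighted sample
    treatment remains associated with ``B``, and omitting it would
    reintroduce baseline confounding.  The ATE contrast is unaffected by
    the adjustment terms (no effect modification in the MSM).
    """
    if isinstance(weights, WeightVector):
        w = weights.final()
        kind = weight_kind or weights.kind
    else:
        w = np.asarray(weights, dtype=float)
        kind = weight_kind or "user"
    y = panel.y[:, -1]
    use = np.isfinite(w) & np.isfinite(y) & (panel.r_y[:, -1] == 1)
    if not np.any(use):
        raise ValueError("no usable persons for the MSM (all censored or unweighted)")
    if np.any(w[use] <= 0):
        raise ValueError("MSM weights must be strictly positive")
    A = panel.a[use, 1:].astype(float)
    if np.any(A.min(axis=0) == A.max(axis=0)):
        t_bad = 1 + int(np.argmax(A.min(axis=0) == A.max(axis=0)))
        raise ValueError(
            f"treatment column at visit {t_bad} is constant among analyzed persons; "
            "positivity violated in the weighted sample"
        )
    k_a = A.shape[1]
    if adjust_baseline:
        X = sm.add_constant(
            np.column_stack([A, panel.b_cont[use], panel.b_bin[use].astype(float)]),
            has_constant="add",
        )
    else:
        X = sm.add_constant(A, has_constant="add")
    res = sm.WLS(y[use], X, weights=w[use]).fit(cov_type="HC0")
    ws = w[use]
    stats = {"mean": float(ws.mean()), "sd": float(ws.std(ddof=1)), "max": float(ws.max())}
    return MSMFit(
        alpha=float(res.params[0]),
        beta=np.asarray(res.params[1:1 + k_a]),
        cov=np.asarray(res.cov_params())[:1 + k_a, :1 + k_a],
        weight_kind=kind,
        n_ids=int(use.sum()),
        weight_stats=stats,
    )


def ate_always_vs_never(fit: MSMFit) -> tuple:
    """Always-treat vs never-treat contrast: sum of the beta_t, with SE."""
    contrast = np.ones(fit.beta.size)
    est = float(contrast @ fit.beta)
    se = float(np.sqrt(contrast @ fit.beta_cov @ contrast))
    return est, se


def bootstrap_ci(
    panel: Panel,
    pipeline: Callable[[Panel], float],
    b_boot: int = 1000,
    seed=0,
    alpha: float = 0.05,
):
    """Nonparametric percentile CI by resampling persons.

    ``pipeline`` maps a panel to a scalar estimate (typically the full
    weighting-plus-MSM analysis).  Failing resamples are recorded and
    skipped.  Intended for single-dataset analyses; too expensive to run
    inside the simulation harness.
    """
    rng = np.random.default_rng(seed)
    n = panel.n
    estimates = []
    failures = 0
    for _ in range(b_boot):
        idx = rng.integers(0, n, n)
        boot = Panel(
            b_bin=panel.b_bin[idx], b_cont=panel.b_cont[idx],
            x=panel.x[idx], a=panel.a[idx], y=panel.y[idx],
            r_x=panel.r_x[idx], r_y=panel.r_y[idx], c=panel.c[idx],
        )
        try:
            estimates.append(pipeline(boot))
        except Exception:
            failures += 1
    if not estimates:
        raise RuntimeError("every bootstrap resample failed")
    lo, hi = np.quantile(estimates, [alpha / 2, 1 - alpha / 2])
    return {
        "lower": float(lo),
        "upper": float(hi),
        "n_success": len(estimates),
        "n_failures": failures,
    }
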