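"""Vectorized logistic regression (IRLS) used by the weight models.

The simulation harness fits a few dozen pooled logistic models per
replication; this module provides a thin Newton/IRLS solver with the
minimal diagnostics the weighting code needs (separation and degenerate
responses).  It is cross-validated against statsmodels GLM in the test
suite.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class SeparationError(RuntimeError):
    """Raised when the likelihood appears unbounded (perfect separation)."""


class DegenerateResponseError(RuntimeError):
    """Raised when all responses are identical (probability 0 or 1)."""


def fit_logit(
    X: np.ndarray,
    y: np.ndarray,
    ridge: float = 0.0,
    max_iter: int = 40,
    tol: float = 1e-10,
):
    """Maximum-likelihood logistic fit.

    Returns ``(beta, cov)`` where ``cov`` is the inverse observed Fisher
    information.  ``ridge`` adds an L2 penalty (used as a fallback under
    separation).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"logistic fit needs more rows ({n}) than parameters ({k})")
    if y.min() == y.max():
        raise DegenerateResponseError("all responses identical; probability is degenerate")

    beta = np.zeros(k)
    dev_old = np.inf
    pen = ridge * np.eye(k)
    pen[0, 0] = 0.0  # never penalize the intercept
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        p = np.clip(p, 1e-12, 1 - 1e-12)
        w = p * (1 - p)
        z = eta + (y - p) / w
        XtW = X.T * w
        H = XtW @ X + pen
        try:
            beta_new = np.linalg.solve(H, XtW @ z)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - pathological design
            raise SeparationError(f"singular information matrix: {exc}") from exc
        dev = -2.0 * np.sum(y * np.log(p) + (1 - y) * np.log1p(-p))
        step = beta_new - beta
        beta = beta_new
        if not np.all(np.isfinite(beta)):
            raise SeparationError("non-finite coefficients during IRLS")
        if abs(dev_old - dev) < tol * (abs(dev) + 1.0) and np.max(np.abs(step)) < 1e-8:
            break
        dev_old = dev
    else:
        if np.max(np.abs(X @ beta)) > 30:
            raise SeparationError("IRLS did not converge; linear predictor diverging")
    if ridge == 0.0 and np.max(np.abs(X @ beta)) > 30:
        raise SeparationError("fitted log-odds exceed +/-30; data are (quasi-)separated")

    eta = X @ beta
    p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    w = p * (1 - p)
    cov = np.linalg.inv((X.T * w) @ X + pen)
    return beta, cov
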