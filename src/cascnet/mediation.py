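"""Single-mediator path analysis with bias-corrected bootstrap inference.

The model quantifies how much of the lesion-burden effect on cognition
flows through grey-matter volume: with standardized X (WMH volume),
M (global GMV) and Y (cognitive score), two least-squares regressions

    M = a·X + C·γ₁ + e₁
    Y = c′·X + b·M + C·γ₂ + e₂

give the mediated (indirect) effect a·b, the direct effect c′ and the
total effect c′ + a·b (exact for a single mediator when both equations
share the covariate set C). Least squares coincides with maximum
likelihood for this saturated recursive system. Confidence intervals use
the bias-corrected percentile bootstrap over case resamples.
"""

from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
from scipy.special import ndtr, ndtri

from .types import MediationResult


def inverse_tmt(tmt_a):
    """Reciprocal of TMT-A completion time, so higher = better."""
    t = np.asarray(tmt_a, dtype=float)
    if (t <= 0).any():
        raise ValueError("TMT-A times must be strictly positive")
    out = 1.0 / t
    return float(out) if out.ndim == 0 else out


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant variable")
    return (v - v.mean()) / sd


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def fit_paths(x: np.ndarray, m: np.ndarray, y: np.ndarray,
              covariates: Optional[np.ndarray] = None,
              outcome: str = "") -> MediationResult:
    """Point estimates of the standardized mediation paths.

    x, m, y are z-standardized internally; covariates (subjects × p)
    enter both regressions unstandardized with an intercept.
    """
    x = _zscore(np.asarray(x, dtype=float))
    m = _zscore(np.asarray(m, dtype=float))
    y = _zscore(np.asarray(y, dtype=float))
    n = x.size
    if not (m.size == n == y.size):
        raise ValueError("x, m, y must be equally long")
    C = np.ones((n, 1))
    cov_names: list = []
    if covariates is not None:
        cc = np.asarray(covariates, dtype=float)
        if cc.ndim == 1:
            cc = cc[:, None]
        C = np.column_stack([C, cc])
        cov_names = [f"c{i}" for i in range(cc.shape[1])]
    a = float(_ols(np.column_stack([x, C]), m)[0])
    beta_y = _ols(np.column_stack([x, m, C]), y)
    c_prime, b = float(beta_y[0]), float(beta_y[1])
    return MediationResult(a=a, b=b, c_prime=c_prime, outcome=outcome,
                           covariates=cov_names, n=n)


def total_effect(x: np.ndarray, y: np.ndarray,
                 covariates: Optional[np.ndarray] = None) -> float:
    """Coefficient of standardized X in Y ~ X + C (the reduced-form total)."""
    x = _zscore(np.asarray(x, dtype=float))
    y = _zscore(np.asarray(y, dtype=float))
    C = np.ones((x.size, 1))
    if covariates is not None:
        cc = np.asarray(covariates, dtype=float)
        if cc.ndim == 1:
            cc = cc[:, None]
        C = np.column_stack([C, cc])
    return float(_ols(np.column_stack([x, C]), y)[0])


def _bc_interval(boot: np.ndarray, estimate: float, level: float = 0.95):
    """Bias-corrected percentile interval (no acceleration term)."""
    B = boot.size
    prop = np.clip(np.mean(boot < estimate), 1.0 / (B + 1), B / (B + 1.0))
    z0 = ndtri(prop)
    zc = ndtri(0.5 + level / 2.0)
    lo = float(np.quantile(boot, ndtr(2 * z0 - zc)))
    hi = float(np.quantile(boot, ndtr(2 * z0 + zc)))
    return lo, hi


def bootstrap_indirect(x: np.ndarray, m: np.ndarray, y: np.ndarray,
                       covariates: Optional[np.ndarray] = None,
                       n_boot: int = 5000, seed: int = 0,
                       outcome: str = "",
                       level: float = 0.95) -> MediationResult:
    """Case-resampling bootstrap CIs for indirect, direct and total effects.

    Effects are significant when their bias-corrected ``level`` interval
    excludes zero. Resamples whose regressions fail (degenerate designs)
    are redrawn; more than 1% failures aborts.
    """
    if n_boot < 1000:
        raise ValueError("need at least 1000 bootstrap resamples")
    x = np.asarray(x, dtype=float)
    m = np.asarray(m, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.ndim == 1:
        cov = cov[:, None]
    point = fit_paths(x, m, y, cov, outcome=outcome)
    n = x.size
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, 3))     # indirect, direct, total
    failures = 0
    i = 0
    while i < n_boot:
        idx = rng.integers(0, n, n)
        try:
            r = fit_paths(x[idx], m[idx], y[idx],
                          None if cov is None else cov[idx])
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
            if failures > max(10, 0.01 * n_boot):
                raise RuntimeError("bootstrap refit failure rate exceeds 1%")
            continue
        boot[i] = (r.indirect, r.c_prime, r.total)
        i += 1
    ci = {
        "indirect": _bc_interval(boot[:, 0], point.indirect, level),
        "direct": _bc_interval(boot[:, 1], point.c_prime, level),
        "total": _bc_interval(boot[:, 2], point.total, level),
    }
    point.ci = ci
    point.n_boot = n_boot
    point.seed = seed
    return point


def effect_proportions(c_prime: float, indirect: float):
    """Percent shares of direct and indirect effects in the total.

    When the two effects share a sign the shares add to 100%. With
    opposite signs (inconsistent mediation) the raw ratios are returned
    with a warning, since percentages of a partially cancelled total are
    not proportions.
    """
    total = c_prime + indirect
    if total == 0:
        raise ValueError("total effect is zero; proportions undefined")
    if c_prime * indirect < 0:
        warnings.warn("direct and indirect effects have opposite signs; "
                      "proportions are unnormalized", stacklevel=2)
    return 100.0 * c_prime / total, 100.0 * indirect / total
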