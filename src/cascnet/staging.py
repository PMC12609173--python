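"""Severity staging of patients by lesion volume.

Two strategies: data-driven changepoints of the grey-matter-volume vs
lesion-volume relationship, or the modified Fazekas grade. The
changepoint procedure fits a locally-weighted quadratic (loess-style)
regression of global GMV on WMH volume, then approximates the smoothed
curve with a continuous 4-segment piecewise-linear function by
exhaustive breakpoint search; the three breakpoints are the stage
thresholds. Stages are right-closed intervals: stage I is [0, t1],
stage II (t1, t2], stage III (t2, t3], stage IV (t3, inf).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

STAGE_LABELS = ("I", "II", "III", "IV")


@dataclass
class StageModel:
    thresholds: tuple          # 3 increasing WMH volumes (mL)
    method: str                # "local_polynomial" or "fazekas"

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) != 3 or not (t[0] < t[1] < t[2]):
            raise ValueError("need 3 strictly increasing thresholds")


def _loess_quadratic(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray,
                     span: float) -> np.ndarray:
    """Tricube-weighted local quadratic regression evaluated at x_eval."""
    n = x.size
    k = max(int(np.ceil(span * n)), 5)
    out = np.empty(x_eval.size)
    for i, x0 in enumerate(x_eval):
        d = np.abs(x - x0)
        h = np.partition(d, k - 1)[k - 1]
        if h == 0:
            h = np.finfo(float).eps
        w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
        sel = w > 0
        X = np.column_stack([np.ones(sel.sum()), x[sel] - x0,
                             (x[sel] - x0) ** 2])
        sw = np.sqrt(w[sel])
        beta, *_ = np.linalg.lstsq(X * sw[:, None], y[sel] * sw, rcond=None)
        out[i] = beta[0]
    return out


def _piecewise_linear_fit(x: np.ndarray, y: np.ndarray, breaks: Sequence[float]):
    """Continuous piecewise-linear least squares via hinge basis; returns SSE."""
    X = np.column_stack([np.ones_like(x), x] +
                        [np.clip(x - b, 0.0, None) for b in breaks])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def fit_stage_thresholds(wmh: np.ndarray, global_gmv: np.ndarray,
                         span: float = 0.5, n_grid: int = 40) -> tuple:
    """Three WMH changepoints of the smoothed GMV–WMH curve.

    The loess-smoothed curve is evaluated on a dense grid and
    approximated by the best continuous 4-segment piecewise-linear
    function (exhaustive search over breakpoint triples drawn from
    ``n_grid`` interior quantile-spaced candidates, minimizing squared
    error).
    """
    wmh = np.asarray(wmh, dtype=float)
    gmv = np.asarray(global_gmv, dtype=float)
    if wmh.size < 20:
        raise ValueError("need at least 20 patients to fit stages")
    if span <= 0:
        raise ValueError("span must be positive")
    if np.ptp(gmv) == 0:
        raise ValueError("global GMV is constant")
    order = np.argsort(wmh, kind="stable")
    x, y = wmh[order], gmv[order]
    x_dense = np.linspace(x.min(), x.max(), 200)
    smooth = _loess_quadratic(x, y, x_dense, span)

    candidates = np.quantile(x, np.linspace(0.05, 0.95, n_grid))
    candidates = np.unique(candidates)
    best_sse, best = np.inf, None
    for triple in combinations(candidates, 3):
        sse = _piecewise_linear_fit(x_dense, smooth, triple)
        if sse < best_sse - 1e-15:
            best_sse, best = sse, triple
    return tuple(float(b) for b in best)


def assign_stages(wmh: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    """Stage labels I–IV from lesion volume; intervals right-closed."""
    t1, t2, t3 = thresholds
    if not t1 < t2 < t3:
        raise ValueError("thresholds must be strictly increasing")
    wmh = np.asarray(wmh, dtype=float)
    if (wmh < 0).any():
        raise ValueError("lesion volumes must be non-negative")
    idx = np.searchsorted([t1, t2, t3], wmh, side="left")
    # searchsorted 'left' puts wmh == t exactly at the lower stage
    return np.array([STAGE_LABELS[i] for i in idx])


def group_by_fazekas(fazekas: Sequence[int]) -> np.ndarray:
    """Identity mapping of Fazekas grades 1–3 to stages I–III."""
    grades = np.asarray(fazekas, dtype=int)
    if ((grades < 1) | (grades > 3)).any():
        raise ValueError("patient Fazekas grades must lie in 1-3")
    return np.array([STAGE_LABELS[g - 1] for g in grades])
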