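"""Causal structural covariance network (CaSCN) core.

Cross-sectional grey-matter maps are ordered by lesion burden into a
pseudo-time series; directed influence from a seed region is then
estimated voxel-wise with a signed-path-coefficient Granger causality
(GC): both series are z-standardized and the lag-1 regression

    y_t = alpha + rho * y_{t-1} + beta * x_{t-1} + eps_t

is solved by least squares. ``beta`` — the coefficient of the lagged
exogenous series — is the signed GC value: positive values mean atrophy
in x precedes atrophy in y (propagation), negative values mean atrophy
in x precedes density *gain* in y (compensation).
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .config import AnalysisConfig
from .types import Cluster, ClusterSet, GCMap, GMVImageSet, PseudoTimeSeries, Region
from .simulate import wmh_rank_order

_CONN26 = np.ones((3, 3, 3), dtype=bool)

DEFAULT_COVARIATES = ("age", "sex", "education_years", "tiv")


def _design_from_cohort(cohort: pd.DataFrame, covariates: Sequence[str]) -> np.ndarray:
    cols = [np.ones(len(cohort))]
    for name in covariates:
        v = cohort[name]
        if v.dtype == object or str(v.dtype) == "category":
            v = pd.factorize(v)[0]
        cols.append(np.asarray(v, dtype=float))
    return np.column_stack(cols)


def residualize_covariates(matrix: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Per-feature least-squares residuals of ``matrix`` on ``covariates``.

    ``covariates`` must include an intercept column and be full rank.
    """
    X = np.asarray(covariates, dtype=float)
    if X.ndim != 2 or X.shape[0] != matrix.shape[0]:
        raise ValueError("covariate design must be subjects × p")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate design is rank deficient")
    beta, *_ = np.linalg.lstsq(X, matrix, rcond=None)
    return matrix - X @ beta


def build_pseudo_timeseries(data: Union[GMVImageSet, np.ndarray],
                            cohort: pd.DataFrame,
                            covariates: Sequence[str] = DEFAULT_COVARIATES,
                            ) -> PseudoTimeSeries:
    """Residualize grey-matter features and order patients by lesion burden.

    ``data`` is either a :class:`GMVImageSet` (rows matched to the cohort
    by subject_id) or a subjects × features matrix aligned with the
    cohort's rows. Controls in the cohort are ignored; rows are sorted by
    ascending WMH volume with subject_id as tie-break.
    """
    cohort = cohort.reset_index(drop=True)
    pat = cohort[cohort["group"] == "patient"].reset_index(drop=True)
    if len(pat) == 0:
        raise ValueError("cohort contains no patients")
    if pat["wmh_volume"].isna().any():
        raise ValueError("missing WMH volumes")

    mask = None
    if isinstance(data, GMVImageSet):
        pos = {s: i for i, s in enumerate(data.subject_ids)}
        missing = [s for s in pat["subject_id"] if s not in pos]
        if missing:
            raise ValueError(f"images missing for subjects: {missing[:5]}")
        rows = [pos[s] for s in pat["subject_id"]]
        matrix = data.masked_matrix()[rows]
        mask = data.mask
    else:
        matrix = np.asarray(data, dtype=float)
        if matrix.shape[0] == len(cohort):
            matrix = matrix[(cohort["group"] == "patient").to_numpy()]
        if matrix.shape[0] != len(pat):
            raise ValueError("feature matrix rows do not match patients")

    X = _design_from_cohort(pat, covariates)
    resid = residualize_covariates(matrix, X)
    order = wmh_rank_order(pat)
    return PseudoTimeSeries(
        data=resid[order],
        ordering=order,
        subject_ids=list(pat["subject_id"].to_numpy()[order]),
        wmh=pat["wmh_volume"].to_numpy(dtype=float)[order],
        mask=mask,
        covariates=list(covariates),
    )


def extract_seed_series(pts: PseudoTimeSeries,
                        seed: Union[Region, np.ndarray]) -> np.ndarray:
    """Mean residual grey-matter value over seed voxels per pseudo-time point."""
    if pts.mask is None:
        raise ValueError("pseudo-time series has no voxel geometry")
    seed_mask = seed.mask(pts.mask.shape) if isinstance(seed, Region) \
        else np.asarray(seed, dtype=bool)
    cols = seed_mask[pts.mask]
    if not cols.any():
        raise ValueError("seed region does not intersect the analysis mask")
    return pts.data[:, cols].mean(axis=1)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("series is constant")
    return (x - x.mean()) / sd


def signed_gc_pair(x: np.ndarray, y: np.ndarray, order: int = 1) -> float:
    """Signed path coefficient of lagged x in the GC regression for y.

    Both series are z-standardized; y_t is regressed on an intercept,
    its own first ``order`` lags and the first ``order`` lags of x. The
    returned value is the sum of the lagged-x coefficients (for the
    default order 1, exactly the single coefficient beta).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and equally long")
    T = x.size
    if T < 10:
        raise ValueError("need at least 10 time points")
    if T <= 2 * order + 1:
        raise ValueError("series too short for requested order")
    xs, ys = _standardize(x), _standardize(y)
    cols = [np.ones(T - order)]
    for k in range(1, order + 1):
        cols.append(ys[order - k:T - k])
    for k in range(1, order + 1):
        cols.append(xs[order - k:T - k])
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, ys[order:], rcond=None)
    return float(beta[1 + order:].sum())


def _gc_seed_to_voxels(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Vectorized beta of x_{t-1} in y_t ~ 1 + y_{t-1} + x_{t-1}, per column.

    x is the standardized seed series, Y a standardized T × V matrix.
    Columns with (numerically) collinear regressors return NaN.
    """
    y0 = Y[1:]                      # y_t
    y1 = Y[:-1]                     # y_{t-1}
    x1 = x[:-1]                     # x_{t-1}
    y0 = y0 - y0.mean(axis=0)
    y1 = y1 - y1.mean(axis=0)
    x1 = x1 - x1.mean()
    S11 = np.einsum("tv,tv->v", y1, y1)
    Sx1 = y1.T @ x1
    Sxx = float(x1 @ x1)
    S10 = np.einsum("tv,tv->v", y1, y0)
    Sx0 = y0.T @ x1
    det = S11 * Sxx - Sx1 ** 2
    scale = np.maximum(S11 * Sxx, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (S11 * Sx0 - Sx1 * S10) / det
    beta[np.abs(det) <= 1e-12 * scale] = np.nan
    return beta


def _gc_voxels_to_seed(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized beta of x_{t-1} in y_t ~ 1 + y_{t-1} + x_{t-1}, x per column."""
    y0 = y[1:] - y[1:].mean()
    y1 = y[:-1] - y[:-1].mean()
    x1 = X[:-1]
    x1 = x1 - x1.mean(axis=0)
    S11 = float(y1 @ y1)
    Sx1 = x1.T @ y1
    Sxx = np.einsum("tv,tv->v", x1, x1)
    S10 = float(y1 @ y0)
    Sx0 = x1.T @ y0
    det = S11 * Sxx - Sx1 ** 2
    scale = np.maximum(S11 * Sxx, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (S11 * Sx0 - Sx1 * S10) / det
    beta[np.abs(det) <= 1e-12 * scale] = np.nan
    return beta


def _standardize_columns(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0, ddof=1)
    out = np.full_like(M, np.nan)
    ok = sd > 0
    out[:, ok] = (M[:, ok] - M[:, ok].mean(axis=0)) / sd[ok]
    return out


def _gc_fields(seed_series: np.ndarray, data: np.ndarray):
    """Both-direction GC values for every column of ``data``."""
    xs = _standardize(seed_series)
    Ys = _standardize_columns(data)
    fwd = np.full(data.shape[1], np.nan)
    rev = np.full(data.shape[1], np.nan)
    ok = ~np.isnan(Ys).any(axis=0)
    fwd[ok] = _gc_seed_to_voxels(xs, Ys[:, ok])
    rev[ok] = _gc_voxels_to_seed(Ys[:, ok], xs)
    return fwd, rev


def voxelwise_cascn(pts: PseudoTimeSeries, seed_series: np.ndarray,
                    seed: Optional[Region] = None):
    """Seed-based signed GC maps in both directions.

    Returns ``(seed_to_target, target_to_seed)`` :class:`GCMap` objects;
    voxels with constant or collinear series are NaN (undefined).
    """
    if pts.mask is None or not pts.mask.any():
        raise ValueError("empty mask")
    fwd, rev = _gc_fields(seed_series, pts.data)
    maps = []
    for vals, direction in ((fwd, "seed_to_target"), (rev, "target_to_seed")):
        grid = np.full(pts.mask.shape, np.nan)
        grid[pts.mask] = vals
        maps.append(zscore_map(GCMap(gc=grid, mask=pts.mask,
                                     direction=direction, seed=seed)))
    return tuple(maps)


def zscore_map(gcmap: GCMap) -> GCMap:
    """Standardize the GC map to zero mean / unit sd over defined voxels."""
    vals = gcmap.gc[gcmap.mask]
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError("need at least 2 defined voxels")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("GC map is constant inside the mask")
    z = (gcmap.gc - vals.mean()) / sd
    z[~gcmap.mask] = np.nan
    gcmap.z = z
    return gcmap


def label_clusters(stat: np.ndarray, passing: np.ndarray,
                   min_extent: int = 0) -> list:
    """26-connected clusters of ``passing`` voxels, filtered by extent.

    Returns :class:`Cluster` objects with peak = voxel of maximal |stat|.
    """
    labels, n = ndimage.label(passing, structure=_CONN26)
    clusters = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        if len(vox) <= min_extent:
            continue
        vals = stat[tuple(vox.T)]
        peak_i = int(np.argmax(np.abs(vals)))
        clusters.append(Cluster(
            id=len(clusters) + 1, voxels=vox, peak=tuple(vox[peak_i]),
            peak_stat=float(vals[peak_i]), extent=len(vox),
            sign=int(np.sign(vals[peak_i]))))
    return clusters


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(p, method="bh")


def _voxel_pass(gcmap: GCMap, config: AnalysisConfig) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return (np.abs(gcmap.z) > config.z_threshold) \
            & (np.abs(gcmap.gc) > config.gc_threshold) & gcmap.mask


def threshold_cascn(gcmap: GCMap, pts: PseudoTimeSeries,
                    seed_region: Union[Region, np.ndarray],
                    config: Optional[AnalysisConfig] = None,
                    n_perm: Optional[int] = None,
                    seed: int = 0) -> ClusterSet:
    """Cluster-level inference on a thresholded GC map.

    Voxels pass when |z| > ``z_threshold`` and |GC| > ``gc_threshold``;
    26-connected clusters larger than ``min_cluster_voxels`` are tested
    against a permutation null of the maximum supra-threshold cluster
    mass (sum of |GC|) obtained by re-randomizing the pseudo-time order,
    and corrected across clusters with Benjamini–Hochberg FDR. Positive
    and negative clusters are kept separate by construction (a cluster's
    sign is the sign of its voxels' GC values).
    """
    cfg = config or AnalysisConfig()
    n_perm = n_perm if n_perm is not None else cfg.n_perm
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")

    passing = _voxel_pass(gcmap, cfg)
    pos = label_clusters(gcmap.gc, passing & (gcmap.gc > 0), cfg.min_cluster_voxels)
    neg = label_clusters(gcmap.gc, passing & (gcmap.gc < 0), cfg.min_cluster_voxels)
    clusters = pos + neg
    for i, c in enumerate(clusters):
        c.id = i + 1
    if not clusters:
        return ClusterSet([])

    masses = np.array([np.abs(gcmap.gc[tuple(c.voxels.T)]).sum() for c in clusters])

    rng = np.random.default_rng(seed)
    T = pts.n_time
    reverse = gcmap.direction == "target_to_seed"
    seed_mask = (seed_region.mask(pts.mask.shape) if isinstance(seed_region, Region)
                 else np.asarray(seed_region, dtype=bool))
    seed_cols = seed_mask[pts.mask]
    null_max = np.zeros(n_perm)
    for b in range(n_perm):
        idx = rng.permutation(T)
        data_p = pts.data[idx]
        x_p = data_p[:, seed_cols].mean(axis=1)
        xs = _standardize(x_p)
        Ys = _standardize_columns(data_p)
        ok = ~np.isnan(Ys).any(axis=0)
        vals = np.full(data_p.shape[1], np.nan)
        if reverse:
            vals[ok] = _gc_voxels_to_seed(Ys[:, ok], xs)
        else:
            vals[ok] = _gc_seed_to_voxels(xs, Ys[:, ok])
        finite = vals[np.isfinite(vals)]
        if finite.size < 2 or finite.std(ddof=1) == 0:
            continue
        zvals = (vals - finite.mean()) / finite.std(ddof=1)
        with np.errstate(invalid="ignore"):
            vpass = (np.abs(zvals) > cfg.z_threshold) \
                & (np.abs(vals) > cfg.gc_threshold)
        grid_pass = np.zeros(pts.mask.shape, dtype=bool)
        grid_pass[pts.mask] = vpass
        grid_vals = np.zeros(pts.mask.shape)
        grid_vals[pts.mask] = np.where(np.isfinite(vals), np.abs(vals), 0.0)
        labels, nlab = ndimage.label(grid_pass, structure=_CONN26)
        if nlab:
            sums = ndimage.sum_labels(grid_vals, labels, np.arange(1, nlab + 1))
            null_max[b] = sums.max()

    p = np.array([(1.0 + np.sum(null_max >= m)) / (n_perm + 1.0) for m in masses])
    q = _bh_adjust(p)
    for c, pi, qi in zip(clusters, p, q):
        c.p, c.q = float(pi), float(qi)
    return ClusterSet(clusters)
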