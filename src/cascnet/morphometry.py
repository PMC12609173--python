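"""Mass-univariate morphometry statistics with permutation cluster inference.

Implements the voxel-based morphometry (VBM) style group contrast — a
per-voxel general linear model of grey-matter density on a group
indicator plus nuisance covariates — together with the summary-statistic
tests used for cohort tables (pooled two-sample t, 2×2 chi-square) and
the grey-matter mask threshold selection.

Cluster-level inference is nonparametric: supra-threshold voxels (at a
two-sided forming p) are grouped at 26-connectivity, and each cluster's
mass (sum of |t|) is referred to a permutation null of the maximum
cluster mass obtained by re-randomizing the exchangeable group labels;
Benjamini–Hochberg FDR is then applied across clusters.

The per-voxel t for the group coefficient uses the Frisch–Waugh–Lovell
partialling identity: residualize the data and the (permuted) group
indicator against the nuisance design once, then the GLM t equals the
simple-regression t between the residuals with df = n − p − 1. This is
algebraically exact and lets every permutation reuse the residualized
data.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .cascn import _bh_adjust, label_clusters
from .types import ClusterSet, GMVImageSet, TMap

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def summary_two_sample_t(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int):
    """Pooled-variance Student t from group summary statistics.

    Returns ``(t, df, p)`` with t = (mean1 − mean2) / se, df = n1+n2−2
    and a two-sided p-value.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / df
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    t = (mean1 - mean2) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), int(df), float(p)


def chi_square_2x2(a: int, b: int, c: int, d: int):
    """Pearson chi-square (df = 1, no continuity correction) for a 2×2 table.

    Closed form N(ad − bc)² / [(a+b)(c+d)(a+c)(b+d)].
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(m == 0 for m in margins):
        raise ValueError("all table margins must be positive")
    stat = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    p = stats.chi2.sf(stat, df=1)
    return float(stat), float(p)


def _as_matrix(images: Union[GMVImageSet, np.ndarray]):
    if isinstance(images, GMVImageSet):
        return images.masked_matrix(), images.mask
    Y = np.asarray(images, dtype=float)
    return Y, None


def _fwl_tmap(Y_resid: np.ndarray, g_resid: np.ndarray, df: int) -> np.ndarray:
    """t for the group coefficient from FWL residuals (vectorized)."""
    gn = g_resid / np.linalg.norm(g_resid)
    num = Y_resid.T @ gn
    ss = np.einsum("tv,tv->v", Y_resid, Y_resid)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = num ** 2 / ss
        t = np.sign(num) * np.sqrt(r2 * df / np.maximum(1.0 - r2, 1e-300))
    t[~np.isfinite(t)] = 0.0
    return t


def _residualize(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, M, rcond=None)
    return M - Z @ beta


def _group_indicator(group: Sequence, positive_level=None) -> np.ndarray:
    labels = pd.Series(list(group))
    levels = labels.unique()
    if len(levels) != 2:
        raise ValueError("group must have exactly 2 levels")
    pos = positive_level if positive_level is not None else levels[0]
    if pos not in set(levels):
        raise ValueError(f"positive_level {pos!r} not among group labels")
    return (labels == pos).to_numpy(dtype=float)


def voxelwise_glm_ttest(images: Union[GMVImageSet, np.ndarray],
                        group: Sequence,
                        covariates: Optional[np.ndarray] = None,
                        contrast: str = "group",
                        positive_level=None) -> TMap:
    """Per-voxel GLM t for the group coefficient, covariate-adjusted.

    ``group`` is any two-level labeling; the indicator is 1 for
    ``positive_level`` (default: the first level encountered), so t > 0
    means that level has the larger adjusted mean. ``covariates`` is a
    subjects × p matrix (intercept added automatically).
    """
    Y, mask = _as_matrix(images)
    g = _group_indicator(group, positive_level)
    if min((g == 0).sum(), (g == 1).sum()) < 2:
        raise ValueError("need at least 2 subjects per group")
    n = Y.shape[0]
    Z = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.column_stack([Z, C])
    X_full = np.column_stack([Z, g])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("design matrix is rank deficient")
    df = n - X_full.shape[1]
    t = _fwl_tmap(_residualize(Y, Z), _residualize(g[:, None], Z)[:, 0], df)
    if mask is not None:
        grid = np.full(mask.shape, np.nan)
        grid[mask] = t
        return TMap(statistic=grid, mask=mask, df=df, contrast=contrast,
                    covariates=[] if covariates is None else
                    [f"c{i}" for i in range(Z.shape[1] - 1)])
    return TMap(statistic=t, mask=np.ones(t.shape, dtype=bool), df=df,
                contrast=contrast)


def cluster_level_fdr(images: GMVImageSet, group: Sequence,
                      covariates: Optional[np.ndarray] = None,
                      forming_p: float = 0.001, min_extent: int = 0,
                      n_perm: int = 200, seed: int = 0,
                      alpha: float = 0.05, positive_level=None):
    """Group-contrast t-map with permutation cluster-level FDR.

    Returns ``(TMap, ClusterSet)``. Cluster p-values come from a
    permutation null of the maximum supra-threshold cluster mass under
    random relabeling of the exchangeable group labels; q-values are
    BH-adjusted across observed clusters. t > 0 means ``positive_level``
    has the larger adjusted mean.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    Y = images.masked_matrix()
    mask = images.mask
    g = _group_indicator(group, positive_level)
    n = Y.shape[0]
    Z = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.column_stack([Z, C])
    df = n - Z.shape[1] - 1
    t_crit = stats.t.isf(forming_p / 2.0, df)

    Yr = _residualize(Y, Z)
    t_obs = _fwl_tmap(Yr, _residualize(g[:, None], Z)[:, 0], df)
    grid = np.full(mask.shape, np.nan)
    grid[mask] = t_obs
    tmap = TMap(statistic=grid, mask=mask, df=df, contrast="group")

    stat_grid = np.where(np.isfinite(grid), grid, 0.0)
    pos = label_clusters(stat_grid, (stat_grid > t_crit) & mask, min_extent)
    neg = label_clusters(stat_grid, (stat_grid < -t_crit) & mask, min_extent)
    clusters = pos + neg
    for i, cl in enumerate(clusters):
        cl.id = i + 1
    if not clusters:
        return tmap, ClusterSet([])

    masses = np.array([np.abs(stat_grid[tuple(c.voxels.T)]).sum()
                       for c in clusters])
    rng = np.random.default_rng(seed)
    null_max = np.zeros(n_perm)
    abs_grid = np.zeros(mask.shape)
    for b in range(n_perm):
        gp = _residualize(rng.permutation(g)[:, None], Z)[:, 0]
        tp = _fwl_tmap(Yr, gp, df)
        supra = np.abs(tp) > t_crit
        if not supra.any():
            continue
        pass_grid = np.zeros(mask.shape, dtype=bool)
        pass_grid[mask] = supra
        abs_grid[mask] = np.abs(tp)
        labels, nlab = ndimage.label(pass_grid, structure=_CONN26)
        if nlab:
            sums = ndimage.sum_labels(abs_grid, labels, np.arange(1, nlab + 1))
            null_max[b] = sums.max()

    p = np.array([(1.0 + np.sum(null_max >= m)) / (n_perm + 1.0)
                  for m in masses])
    q = _bh_adjust(p)
    for cl, pi, qi in zip(clusters, p, q):
        cl.p, cl.q = float(pi), float(qi)
    return tmap, ClusterSet(clusters)


def select_mask_threshold(mean_probability: np.ndarray, mean_gmv: np.ndarray,
                          candidates: Sequence[float],
                          min_voxels: int = 100) -> float:
    """Pick the probability cut maximizing the probability–density correlation.

    For each candidate c the Pearson correlation between mean tissue
    probability and mean density is evaluated over voxels with
    probability > c; the candidate with the highest correlation wins
    (ties: the smallest such candidate). Candidates retaining fewer than
    ``min_voxels`` voxels are skipped.
    """
    P = np.asarray(mean_probability, dtype=float)
    G = np.asarray(mean_gmv, dtype=float)
    if P.shape != G.shape:
        raise ValueError("probability and density grids must be aligned")
    best_r, best_c = -np.inf, None
    for c in candidates:
        sel = P > c
        if sel.sum() < min_voxels:
            continue
        p, g = P[sel], G[sel]
        if p.std() == 0 or g.std() == 0:
            continue
        r = float(np.corrcoef(p, g)[0, 1])
        if r > best_r + 1e-15:
            best_r, best_c = r, c
    if best_c is None:
        raise ValueError(f"no candidate retains at least {min_voxels} voxels")
    return float(best_c)
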