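"""Synthetic cohorts with planted causal-propagation and mediation truth.

The generator emulates a cross-sectional small-vessel-disease cohort:

* **Phenotypes** (:func:`generate_cohort`): lognormal white-matter
  hyperintensity (WMH) volumes quantile-matched to the study cohort's
  printed median and quartiles; demographics drawn from the printed
  group moments; a global grey-matter volume (GMV) planted with an exact
  in-sample Pearson correlation to WMH volume (default −0.954).
* **Images** (:func:`generate_images`): a homogeneous grey-matter
  template in which a spherical *source* region atrophies with lesion
  burden (density loss = slope · ln(1 + WMH)), and designated *target*
  regions receive that atrophy — scaled by a path weight and shifted by
  a pseudo-time lag along the WMH-ascending subject order — either as
  further loss (propagation, positive weight) or as density gain
  (compensation, negative weight). Controls get template + noise only.
* **Cognition** (:func:`generate_cognition`): scores built from the
  standardized mediation structure score = c′·z(WMH) + b·z(GMV) + ε, so
  the lesion → grey matter → cognition paths are known exactly.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import ndtri

from .config import GeneratorConfig
from .types import COHORT_COLUMNS, GMVImageSet, GroundTruth, Region, validate_cohort

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def wmh_rank_order(cohort: pd.DataFrame) -> np.ndarray:
    """Positional indices of patients sorted by ascending WMH volume.

    Ties are broken lexicographically by subject_id so the pseudo-time
    ordering is deterministic.
    """
    pat = cohort.reset_index(drop=True)
    order = np.lexsort((pat["subject_id"].to_numpy(),
                        pat["wmh_volume"].to_numpy(dtype=float)))
    return order


def default_ground_truth(config: Optional[GeneratorConfig] = None) -> GroundTruth:
    """Planted truth used by the default pipeline: one source, two modules.

    Module 0 is the source-driven propagation chain (source → A1 → A2)
    plus a compensatory (negative-weight) target; module 1 is a second
    chain (B1 → B2 → B3) that the source drives only through a weak link
    to B1, mimicking a hub whose influence crosses into a loosely coupled
    subnetwork.
    """
    cfg = config or GeneratorConfig()
    r = cfg.region_radius
    src = Region("source", (6, 12, 12), r, module=0)
    pos = [
        Region("A1", (12, 6, 12), r, weight=0.9, lag=1, parent="source", module=0),
        Region("A2", (18, 6, 12), r, weight=0.9, lag=1, parent="A1", module=0),
        Region("B1", (12, 18, 12), r, weight=0.3, lag=1, parent="source", module=1),
        Region("B2", (18, 18, 12), r, weight=0.9, lag=1, parent="B1", module=1),
        Region("B3", (18, 12, 18), r, weight=0.9, lag=1, parent="B2", module=1),
    ]
    neg = [Region("comp", (6, 18, 6), r, weight=-0.7, lag=1, parent="source",
                  module=0)]
    return GroundTruth(source=src, positive_targets=pos, negative_targets=neg,
                       atrophy_slope=cfg.atrophy_slope,
                       voxel_noise_sd=cfg.voxel_noise_sd,
                       mediation_coeffs=(cfg.wmh_gmv_r, cfg.dst_b, cfg.dst_c_prime))


def _exact_corr_mixture(x: np.ndarray, r: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance vector with exact in-sample Pearson correlation r to x."""
    zx = (x - x.mean()) / x.std()
    eps = rng.standard_normal(x.size)
    eps = eps - eps.mean() - zx * (eps @ zx) / (zx @ zx) * 1.0
    # re-orthogonalize numerically and normalize
    eps -= zx * (eps @ zx) / (zx @ zx)
    eps /= eps.std()
    return r * zx + np.sqrt(1.0 - r * r) * eps


def _fazekas_from_volume(wmh: np.ndarray) -> np.ndarray:
    """Map lesion volume (mL) to a modified Fazekas grade 1–3.

    Cuts at 5 and 11.5 mL reproduce the study's grade proportions
    (≈ 88 : 52 : 45 of 185) under the default lognormal.
    """
    return np.digitize(wmh, [5.0, 11.5]) + 1


def generate_cohort(n_patients: int, n_controls: int,
                    config: Optional[GeneratorConfig] = None,
                    seed: int = 0) -> pd.DataFrame:
    """Draw a phenotype table of ``n_patients`` patients and ``n_controls`` controls.

    Patients receive lognormal WMH volumes, Fazekas grades derived from
    volume, and a global GMV with exact sample correlation
    ``config.wmh_gmv_r`` to WMH volume. Cognitive scores (dst, tmt_a)
    are left NaN; :func:`generate_cognition` fills them.
    """
    if n_patients < 4 or n_controls < 0:
        raise ValueError("need n_patients >= 4 and n_controls >= 0")
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(seed)

    rows = []
    # stratified (Latin-hypercube) lognormal draws: one uniform per
    # probability stratum, randomly ordered. Marginally each volume is
    # lognormal(mu, sigma), but sample quantiles are pinned to the
    # calibration targets with O(1/n) rather than O(1/sqrt(n)) error.
    u = (rng.permutation(n_patients) + rng.random(n_patients)) / n_patients
    wmh = np.exp(cfg.wmh_mu + cfg.wmh_sigma * ndtri(u))
    gmv_mean, gmv_sd = cfg.patient_moments["gmv"]
    zg = _exact_corr_mixture(wmh, cfg.wmh_gmv_r, rng)
    gmv = gmv_mean + gmv_sd * zg

    for grp, n, moments in (("patient", n_patients, cfg.patient_moments),
                            ("control", n_controls, cfg.control_moments)):
        p_male = 86 / 185 if grp == "patient" else 21 / 40
        tab = pd.DataFrame({
            "subject_id": [f"{'p' if grp == 'patient' else 'c'}{i:04d}"
                           for i in range(n)],
            "group": grp,
            "age": rng.normal(*moments["age"], n).round(1),
            "sex": np.where(rng.random(n) < p_male, "male", "female"),
            "education_years": np.clip(rng.normal(*moments["education"], n), 0,
                                       None).round(1),
            "tiv": rng.normal(*moments["tiv"], n),
            "moca": np.clip(rng.normal(*moments["moca"], n), 0, 30).round(0),
            "mmse": np.clip(rng.normal(*moments["mmse"], n), 0, 30).round(0),
            "dst": np.nan,
            "tmt_a": np.nan,
        })
        if grp == "patient":
            tab["wmh_volume"] = wmh
            tab["fazekas"] = _fazekas_from_volume(wmh)
            tab["global_gmv"] = gmv
        else:
            tab["wmh_volume"] = 0.0
            tab["fazekas"] = 0
            tab["global_gmv"] = rng.normal(*moments["gmv"], n)
        rows.append(tab)

    cohort = pd.concat(rows, ignore_index=True)[COHORT_COLUMNS]
    # dst/tmt_a still NaN; validate the structural invariants
    return validate_cohort(cohort)


def source_atrophy(wmh_sorted: np.ndarray, slope: float) -> np.ndarray:
    """Seed-region density loss per subject: slope · ln(1 + WMH volume)."""
    return slope * np.log1p(wmh_sorted)


def region_atrophy_series(truth: GroundTruth, wmh_sorted: np.ndarray) -> dict:
    """Planted atrophy (density loss) per region along the pseudo-time order.

    A target's series is ``weight × parent series shifted by lag`` with
    zeros for the first ``lag`` subjects; negative weights therefore
    yield density gains. Chained parents compose lags multiplicatively
    in weight and additively in lag.
    """
    base = source_atrophy(wmh_sorted, truth.atrophy_slope)
    series = {truth.source.name: base}
    targets = {t.name: t for t in truth.positive_targets + truth.negative_targets}

    def resolve(name: str) -> np.ndarray:
        if name in series:
            return series[name]
        t = targets[name]
        parent = resolve(t.parent or truth.source.name)
        out = np.zeros_like(parent)
        out[t.lag:] = t.weight * parent[:-t.lag]
        series[name] = out
        return out

    for name in targets:
        resolve(name)
    return series


def _default_affine(shape, voxel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.eye(3) * voxel_size
    aff[:3, 3] = -voxel_size * (np.asarray(shape) - 1) / 2.0
    return aff


def default_mask(shape) -> np.ndarray:
    """All voxels at least one voxel away from the grid boundary."""
    mask = np.zeros(shape, dtype=bool)
    mask[1:-1, 1:-1, 1:-1] = True
    return mask


def generate_images(cohort: pd.DataFrame, truth: GroundTruth,
                    config: Optional[GeneratorConfig] = None,
                    seed: int = 0) -> GMVImageSet:
    """Render per-subject grey-matter density maps with planted propagation.

    Patients are ranked by ascending WMH volume; the source region loses
    density according to :func:`source_atrophy`, and each target region
    applies its parent's atrophy ``lag`` ranks earlier scaled by its path
    weight. Controls receive the unlesioned template. Independent Gaussian
    voxel noise is added and, when ``config.smooth_fwhm_vox`` > 0, maps
    are smoothed with an isotropic Gaussian kernel.
    """
    cfg = config or GeneratorConfig()
    shape = tuple(cfg.grid_shape)
    cohort = cohort.reset_index(drop=True)
    pat_idx = np.flatnonzero((cohort["group"] == "patient").to_numpy())
    truth.validate(shape, len(pat_idx))

    rng = np.random.default_rng(seed)
    n = len(cohort)
    data = np.full((n,) + shape, cfg.baseline_density, dtype=np.float64)

    if cfg.age_slope != 0.0:
        age = cohort["age"].to_numpy(dtype=float)
        data += (-cfg.age_slope * (age - age.mean()))[:, None, None, None] \
            * np.ones(shape)

    order = wmh_rank_order(cohort.iloc[pat_idx])
    ordered_subject_rows = pat_idx[order]
    wmh_sorted = cohort["wmh_volume"].to_numpy(dtype=float)[ordered_subject_rows]
    series = region_atrophy_series(truth, wmh_sorted)

    for region in truth.regions():
        rmask = region.mask(shape)
        delta = series[region.name]          # density loss per rank
        for rank, row in enumerate(ordered_subject_rows):
            data[row][rmask] -= delta[rank]

    if cfg.voxel_noise_sd > 0:
        data += rng.normal(0.0, cfg.voxel_noise_sd, data.shape)
    if cfg.smooth_fwhm_vox > 0:
        sigma = cfg.smooth_fwhm_vox * _FWHM_TO_SIGMA
        for i in range(n):
            data[i] = gaussian_filter(data[i], sigma, mode="nearest")
    np.clip(data, 0.0, 1.5, out=data)

    return GMVImageSet(data=data, mask=default_mask(shape),
                       affine=_default_affine(shape, cfg.voxel_size_mm),
                       subject_ids=list(cohort["subject_id"]))


def generate_cognition(cohort: pd.DataFrame,
                       config: Optional[GeneratorConfig] = None,
                       seed: int = 0,
                       truth: Optional[GroundTruth] = None) -> pd.DataFrame:
    """Fill dst and tmt_a following the planted mediation structure.

    For patients the standardized score is c′·z(WMH) + b·z(GMV) + ε and
    is mapped onto the configured score scale (in-sample, so the patient
    mean/sd match the calibration moments exactly). TMT-A is generated on
    the 1/TMT-A scale — where higher is better, like the digit-symbol
    score — and inverted. Controls draw from their marginal moments.

    When ``truth`` is supplied its ``mediation_coeffs`` (b, c′) override
    the config's digit-symbol paths.
    """
    cfg = config or GeneratorConfig()
    if cohort["global_gmv"].isna().any():
        raise ValueError("global_gmv must be populated before cognition")
    rng = np.random.default_rng(seed)
    out = cohort.reset_index(drop=True).copy()
    pat = out["group"] == "patient"

    dst_b, dst_c = cfg.dst_b, cfg.dst_c_prime
    if truth is not None:
        _, dst_b, dst_c = truth.mediation_coeffs

    wmh = out.loc[pat, "wmh_volume"].to_numpy(dtype=float)
    gmv = out.loc[pat, "global_gmv"].to_numpy(dtype=float)
    zw = (wmh - wmh.mean()) / wmh.std()
    zg = (gmv - gmv.mean()) / gmv.std()
    a = float(np.corrcoef(wmh, gmv)[0, 1])

    def score(b: float, c: float) -> np.ndarray:
        explained = c * c + b * b + 2.0 * a * b * c
        sd_eps = (cfg.cognition_noise_sd if cfg.cognition_noise_sd is not None
                  else np.sqrt(max(1.0 - explained, 0.0)))
        raw = c * zw + b * zg + sd_eps * rng.standard_normal(zw.size)
        if raw.std() == 0:
            return raw
        return (raw - raw.mean()) / raw.std()

    dst_mean, dst_sd = cfg.patient_moments["dst"]
    out.loc[pat, "dst"] = dst_mean + dst_sd * score(dst_b, dst_c)

    tmt_mean, tmt_sd = cfg.patient_moments["tmt_a"]
    inv_mean = 1.0 / tmt_mean
    inv_sd = tmt_sd / tmt_mean ** 2            # delta-method 1/TMT-A scale
    inv = inv_mean + inv_sd * score(cfg.tmt_b, cfg.tmt_c_prime)
    out.loc[pat, "tmt_a"] = 1.0 / np.clip(inv, 1e-4, None)

    ctl = ~pat
    if ctl.any():
        m = cfg.control_moments
        out.loc[ctl, "dst"] = rng.normal(*m["dst"], int(ctl.sum()))
        out.loc[ctl, "tmt_a"] = np.clip(
            rng.normal(*m["tmt_a"], int(ctl.sum())), 1.0, None)
    return validate_cohort(out)


def simulate_study(n_patients: int = 185, n_controls: int = 40,
                   config: Optional[GeneratorConfig] = None,
                   truth: Optional[GroundTruth] = None,
                   seed: int = 0):
    """Full synthetic study: cohort, cognition, images, ground truth.

    Sub-seeds for the three generators are derived from ``seed`` so each
    stage stays individually reproducible.
    """
    cfg = config or GeneratorConfig()
    tr = truth or default_ground_truth(cfg)
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    cohort = generate_cohort(n_patients, n_controls, cfg, seed=seeds[0])
    cohort = generate_cognition(cohort, cfg, seed=seeds[1], truth=None)
    images = generate_images(cohort, tr, cfg, seed=seeds[2])
    return cohort, images, tr
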