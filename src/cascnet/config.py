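"""Configuration objects for analysis and synthetic-cohort generation.

Two dataclasses hold every tunable of the pipeline: :class:`AnalysisConfig`
for the statistical thresholds of the causal structural covariance network
(CaSCN) analysis, and :class:`GeneratorConfig` for the synthetic cohort.
Defaults follow the study conditions the package emulates: a cohort of
185 small-vessel-disease patients with white-matter hyperintensities (WMH)
and 40 healthy controls, voxel-wise grey-matter volume (GMV) maps, and a
lesion-burden-ordered pseudo-time series.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field


@dataclass
class AnalysisConfig:
    """Statistical thresholds for CaSCN and cluster inference.

    Parameters
    ----------
    z_threshold : float
        Voxel-level criterion on the standardized Granger-causality (GC)
        map; |z| > 1.96 corresponds to two-sided p < 0.05.
    gc_threshold : float
        Absolute signed-path-coefficient criterion; edges/voxels with
        |GC| below it are discarded.
    min_cluster_voxels : int
        Minimum cluster extent. The default (200) matches full-resolution
        1.5 mm human data; synthetic desk-scale grids use a smaller value
        via :meth:`desk_scale`.
    fdr_alpha : float
        Benjamini–Hochberg level for cluster-level FDR.
    gc_order : int
        Autoregressive model order of the GC regression. Pseudo-time has
        no physical lag scale, so order 1 is the default.
    bootstrap_n : int
        Bootstrap resamples for mediation confidence intervals.
    mask_threshold : float
        Grey-matter probability cut used to binarize the analysis mask.
    forming_p : float
        Two-sided voxel p forming clusters in the GLM contrast.
    n_perm : int
        Permutations for cluster-level null distributions.
    """

    z_threshold: float = 1.96
    gc_threshold: float = 0.20
    min_cluster_voxels: int = 200
    fdr_alpha: float = 0.05
    gc_order: int = 1
    bootstrap_n: int = 5000
    mask_threshold: float = 0.27
    forming_p: float = 0.001
    n_perm: int = 200

    def __post_init__(self) -> None:
        for name in ("z_threshold", "gc_threshold", "min_cluster_voxels",
                     "bootstrap_n", "mask_threshold", "forming_p", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError(f"fdr_alpha must lie in (0, 1), got {self.fdr_alpha}")
        if self.gc_order < 1:
            raise ValueError("gc_order must be >= 1")

    @classmethod
    def desk_scale(cls, **overrides) -> "AnalysisConfig":
        """Thresholds adapted to the default 24³ synthetic grid.

        Planted regions have radius-2 spheres (~33 voxels), so the
        full-resolution 200-voxel extent criterion would discard every
        true effect; 10 voxels keeps extent filtering meaningful at this
        scale.
        """
        defaults = dict(min_cluster_voxels=10)
        defaults.update(overrides)
        return cls(**defaults)


# Table-calibrated patient / control marginals (volumes in mL).
_PATIENT = dict(age=(57.7, 6.5), education=(10.8, 3.06), tiv=(1424.74, 110.79),
                gmv=(548.92, 25.81), moca=(27.37, 1.28), mmse=(27.94, 1.08),
                dst=(50.63, 18.28), tmt_a=(41.30, 9.91))
_CONTROL = dict(age=(45.5, 7.8), education=(11.5, 5.4), tiv=(1505.07, 147.42),
                gmv=(592.64, 46.92), moca=(27.50, 1.43), mmse=(28.13, 1.07),
                dst=(41.42, 12.33), tmt_a=(54.48, 15.12))


@dataclass
class GeneratorConfig:
    """Synthetic-cohort generator settings.

    WMH volumes are lognormal with parameters obtained by quantile-matching
    the cohort's printed median and quartiles (5.24 [2.64, 11.68] mL):
    location = ln(median), scale = (ln q3 − ln q1) / (2 · z_{0.75}).

    ``wmh_gmv_r`` is the lesion–morphometry coupling: the Pearson
    correlation between WMH volume and global GMV planted in the cohort
    (−0.954 in the study population).

    Image-generator settings: a homogeneous grey-matter template of
    density ``baseline_density`` on a ``grid_shape`` voxel grid, seed
    (source) atrophy of ``atrophy_slope`` density units per log-mL of
    lesion volume, independent voxel noise of sd ``voxel_noise_sd`` and
    optional isotropic Gaussian smoothing with FWHM ``smooth_fwhm_vox``
    voxels (0 disables).
    """

    wmh_median: float = 5.24
    wmh_q1: float = 2.64
    wmh_q3: float = 11.68
    wmh_gmv_r: float = -0.954
    # standardized mediation paths used by generate_cognition:
    # score = c_prime·z(WMH) + b·z(GMV) + noise; defaults give the
    # study's 39%/61% direct/indirect split for DST given a = −0.954.
    dst_b: float = 0.59 / 0.954
    dst_c_prime: float = -0.38
    tmt_b: float = 0.64 / 0.954
    tmt_c_prime: float = -0.32
    patient_moments: dict = field(default_factory=lambda: dict(_PATIENT))
    control_moments: dict = field(default_factory=lambda: dict(_CONTROL))
    # image generator
    grid_shape: tuple = (24, 24, 24)
    voxel_size_mm: float = 6.0
    baseline_density: float = 0.6
    atrophy_slope: float = 0.06
    voxel_noise_sd: float = 0.05
    smooth_fwhm_vox: float = 2.0
    region_radius: int = 2
    age_slope: float = 0.0  # optional density loss per year of age
    # residual sd of the standardized cognition model; None derives it so
    # the standardized score has unit variance under the planted paths
    cognition_noise_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.wmh_q1 < self.wmh_median < self.wmh_q3:
            raise ValueError("WMH quartiles must satisfy 0 < q1 < median < q3")
        if not -1.0 < self.wmh_gmv_r < 1.0:
            raise ValueError("wmh_gmv_r must lie in (-1, 1)")
        if self.voxel_noise_sd < 0 or self.smooth_fwhm_vox < 0:
            raise ValueError("noise sd and smoothing FWHM must be >= 0")
        if self.baseline_density <= 0 or self.atrophy_slope < 0:
            raise ValueError("invalid template settings")

    @property
    def wmh_mu(self) -> float:
        """Lognormal location from the printed median."""
        return math.log(self.wmh_median)

    @property
    def wmh_sigma(self) -> float:
        """Lognormal scale from the printed interquartile range.

        z_{0.75} = 0.674489... is the upper-quartile standard-normal
        deviate, so sigma = (ln q3 − ln q1) / (2 z_{0.75}).
        """
        z75 = 0.6744897501960817
        return (math.log(self.wmh_q3) - math.log(self.wmh_q1)) / (2.0 * z75)


def config_hash(*configs) -> str:
    """Short stable hash of one or more config dataclasses (for provenance)."""
    payload = json.dumps([asdict(c) for c in configs], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
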