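"""Domain containers shared across the pipeline.

Conventions: voxel indices are 0-based (i, j, k); world coordinates are
obtained through the NIfTI affine. Grey-matter density maps are stored as a
``subjects × nx × ny × nz`` float array together with a boolean analysis
mask of the same spatial shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

COHORT_COLUMNS = [
    "subject_id", "group", "wmh_volume", "fazekas", "age", "sex",
    "education_years", "tiv", "global_gmv", "moca", "mmse", "dst", "tmt_a",
]


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort phenotype table in place and return it.

    Enforces the invariants of the cohort schema: unique subject ids,
    patients with fazekas >= 1 and positive lesion volume, controls
    lesion-free, strictly positive TMT-A completion times.
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    dup = table["subject_id"][table["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject_id: {sorted(set(dup))}")
    bad_group = set(table["group"]) - {"patient", "control"}
    if bad_group:
        raise ValueError(f"unknown group labels: {bad_group}")
    pat = table[table["group"] == "patient"]
    ctl = table[table["group"] == "control"]
    if (pat["fazekas"] < 1).any() or (pat["wmh_volume"] <= 0).any():
        raise ValueError("patients must have fazekas >= 1 and wmh_volume > 0")
    if (ctl["wmh_volume"] != 0).any() or (ctl["fazekas"] != 0).any():
        raise ValueError("controls must have wmh_volume == 0 and fazekas == 0")
    if (table["tmt_a"].dropna() <= 0).any():
        raise ValueError("tmt_a must be strictly positive")
    return table


@dataclass
class Region:
    """Spherical region descriptor on the voxel grid.

    ``parent`` names the region whose atrophy drives this one (None for
    the propagation source itself); ``weight`` and ``lag`` define the
    planted causal path from the parent; ``module`` is the planted
    community label used when scoring partition recovery.
    """

    name: str
    center: tuple
    radius: int
    weight: float = 0.0
    lag: int = 0
    parent: Optional[str] = None
    module: Optional[int] = None

    def mask(self, shape: Sequence[int]) -> np.ndarray:
        """Boolean sphere of ``radius`` voxels around ``center``."""
        grids = np.ogrid[tuple(slice(0, s) for s in shape)]
        dist2 = sum((g - c) ** 2 for g, c in zip(grids, self.center))
        return dist2 <= self.radius ** 2


@dataclass
class GroundTruth:
    """Planted causal structure of a synthetic cohort.

    ``positive_targets`` receive atrophy (density loss) proportional to
    their parent's atrophy ``lag`` pseudo-time steps earlier;
    ``negative_targets`` gain density by the same rule (compensation).
    ``mediation_coeffs`` are the standardized paths (a, b, c′) of the
    lesion → grey matter → cognition mediation model.
    """

    source: Region
    positive_targets: list = field(default_factory=list)
    negative_targets: list = field(default_factory=list)
    atrophy_slope: float = 0.06
    voxel_noise_sd: float = 0.05
    mediation_coeffs: tuple = (-0.954, 0.59 / 0.954, -0.38)

    def regions(self) -> list:
        return [self.source] + list(self.positive_targets) + list(self.negative_targets)

    def validate(self, shape: Sequence[int], n_patients: int) -> None:
        masks = [(r.name, r.mask(shape)) for r in self.regions()]
        names = [n for n, _ in masks]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        for i in range(len(masks)):
            if not masks[i][1].any():
                raise ValueError(f"region {masks[i][0]} lies outside the grid")
            for j in range(i + 1, len(masks)):
                if (masks[i][1] & masks[j][1]).any():
                    raise ValueError(
                        f"regions {masks[i][0]} and {masks[j][0]} overlap")
        for t in self.positive_targets + self.negative_targets:
            if t.lag < 1:
                raise ValueError(f"target {t.name} must have lag >= 1")
            if t.lag >= n_patients:
                raise ValueError(f"target {t.name} lag exceeds cohort size")
            if t.parent is not None and t.parent not in names:
                raise ValueError(f"target {t.name} has unknown parent {t.parent}")
        for t in self.positive_targets:
            if t.weight <= 0:
                raise ValueError(f"positive target {t.name} needs weight > 0")
        for t in self.negative_targets:
            if t.weight >= 0:
                raise ValueError(f"negative target {t.name} needs weight < 0")


@dataclass
class GMVImageSet:
    """Aligned per-subject grey-matter density maps plus analysis mask."""

    data: np.ndarray          # (n_subjects, nx, ny, nz)
    mask: np.ndarray          # (nx, ny, nz) boolean
    affine: np.ndarray        # 4×4 voxel→world
    subject_ids: list

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be subjects × 3D grid")
        if self.data.shape[1:] != self.mask.shape:
            raise ValueError("mask shape must match image grid")
        if not self.mask.any():
            raise ValueError("analysis mask is empty")
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError("subject_ids length must match data")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    def masked_matrix(self) -> np.ndarray:
        """subjects × in-mask-voxels matrix (column order = C-order of mask)."""
        return self.data[:, self.mask]

    def global_means(self) -> np.ndarray:
        """Per-subject mean in-mask density."""
        return self.masked_matrix().mean(axis=1)


@dataclass
class TMap:
    """Voxel-wise t statistics for one contrast."""

    statistic: np.ndarray     # 3D, NaN outside mask
    mask: np.ndarray
    df: int
    contrast: str = ""
    covariates: list = field(default_factory=list)


@dataclass
class Cluster:
    id: int
    voxels: np.ndarray        # (k, 3) int voxel indices
    peak: tuple
    peak_stat: float
    extent: int
    p: float = np.nan
    q: float = np.nan
    sign: int = 0


@dataclass
class ClusterSet:
    clusters: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def significant(self, alpha: float = 0.05) -> list:
        return [c for c in self.clusters if np.isfinite(c.q) and c.q < alpha]

    def to_frame(self, affine: Optional[np.ndarray] = None) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            x, y, z = c.peak
            if affine is not None:
                x, y, z = (affine @ np.array([*c.peak, 1.0]))[:3]
            rows.append(dict(cluster_id=c.id, peak_x=x, peak_y=y, peak_z=z,
                             peak_stat=c.peak_stat, n_voxels=c.extent,
                             p=c.p, q=c.q, sign=c.sign))
        return pd.DataFrame(rows, columns=["cluster_id", "peak_x", "peak_y",
                                           "peak_z", "peak_stat", "n_voxels",
                                           "p", "q", "sign"])


@dataclass
class PseudoTimeSeries:
    """Covariate-residualized subject × feature matrix in WMH order.

    Rows are patients sorted by ascending lesion volume (ties broken by
    subject_id), so the row index plays the role of pseudo-time.
    """

    data: np.ndarray          # (T, n_features)
    ordering: np.ndarray      # patient indices into the original table
    subject_ids: list
    wmh: np.ndarray           # sorted lesion volumes
    mask: Optional[np.ndarray] = None   # voxel geometry when features = voxels
    covariates: list = field(default_factory=list)

    @property
    def n_time(self) -> int:
        return self.data.shape[0]


@dataclass
class GCMap:
    """Signed Granger-causality path-coefficient map for one direction."""

    gc: np.ndarray            # 3D, NaN outside mask / undefined voxels
    mask: np.ndarray
    direction: str            # "seed_to_target" or "target_to_seed"
    z: Optional[np.ndarray] = None
    seed: Optional[Region] = None


@dataclass
class MediationResult:
    """Standardized single-mediator path model X → M → Y."""

    a: float
    b: float
    c_prime: float
    outcome: str = ""
    covariates: list = field(default_factory=list)
    ci: dict = field(default_factory=dict)     # effect → (lo, hi)
    n_boot: int = 0
    seed: Optional[int] = None
    n: int = 0

    @property
    def indirect(self) -> float:
        return self.a * self.b

    @property
    def total(self) -> float:
        return self.c_prime + self.indirect

    def proportions(self) -> tuple:
        from .mediation import effect_proportions
        return effect_proportions(self.c_prime, self.indirect)

    def to_dict(self) -> dict:
        out = dict(outcome=self.outcome, a=self.a, b=self.b,
                   c_prime=self.c_prime, indirect=self.indirect,
                   total=self.total, covariates=list(self.covariates),
                   n=self.n, n_boot=self.n_boot, seed=self.seed,
                   ci={k: list(v) for k, v in self.ci.items()})
        try:
            pd_, pi_ = self.proportions()
            out["pct_direct"], out["pct_indirect"] = pd_, pi_
        except ValueError:
            pass
        return out
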