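"""Pseudo-time construction and signed Granger-causality estimation."""

import numpy as np
import pandas as pd
import pytest

from cascnet.cascn import (build_pseudo_timeseries, extract_seed_series,
                           residualize_covariates, signed_gc_pair,
                           threshold_cascn, voxelwise_cascn, zscore_map)
from cascnet.config import AnalysisConfig, GeneratorConfig
from cascnet.simulate import (default_ground_truth, generate_cohort,
                              generate_images)
from cascnet.types import GCMap, Region


def gc_oracle(x, y):
    """Independent normal-equations solution of the lag-1 GC regression."""
    xs = (x - x.mean()) / x.std(ddof=1)
    ys = (y - y.mean()) / y.std(ddof=1)
    X = np.column_stack([np.ones(len(x) - 1), ys[:-1], xs[:-1]])
    beta = np.linalg.solve(X.T @ X, X.T @ ys[1:])
    return beta[2]


class TestResidualize:
    def test_intercept_only_demeans(self, rng):
        m = rng.normal(0, 1, (20, 7))
        out = residualize_covariates(m, np.ones((20, 1)))
        np.testing.assert_allclose(out, m - m.mean(axis=0), atol=1e-12)

    def test_exact_linear_feature_vanishes(self, rng):
        X = np.column_stack([np.ones(30), rng.normal(0, 1, (30, 2))])
        feature = X @ np.array([1.0, -2.0, 0.5])
        out = residualize_covariates(feature[:, None], X)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self, rng):
        X = np.column_stack([np.ones(40), rng.normal(0, 1, (40, 3))])
        out = residualize_covariates(rng.normal(0, 1, (40, 11)), X)
        np.testing.assert_allclose(X.T @ out, 0.0, atol=1e-8)

    def test_rank_deficiency(self, rng):
        X = np.column_stack([np.ones(20), np.ones(20)])
        with pytest.raises(ValueError, match="rank"):
            residualize_covariates(rng.normal(0, 1, (20, 3)), X)


class TestOrdering:
    @staticmethod
    def _cohort(wmh, ids):
        n = len(wmh)
        return pd.DataFrame({
            "subject_id": ids, "group": "patient", "wmh_volume": wmh,
            "fazekas": 1, "age": 55.0, "sex": "male", "education_years": 10.0,
            "tiv": 1400.0, "global_gmv": 550.0, "moca": 27, "mmse": 28,
            "dst": 50.0, "tmt_a": 40.0})

    def test_sorts_by_volume(self):
        c = self._cohort([5.2, 1.1, 14.9], ["s1", "s2", "s3"])
        pts = build_pseudo_timeseries(np.eye(3), c, covariates=())
        assert pts.subject_ids == ["s2", "s1", "s3"]

    def test_ties_broken_by_subject_id(self):
        c = self._cohort([2.0, 2.0, 1.0], ["sb", "sa", "sc"])
        pts = build_pseudo_timeseries(np.eye(3), c, covariates=())
        assert pts.subject_ids == ["sc", "sa", "sb"]

    def test_invariant_to_row_shuffle(self, rng):
        wmh = rng.uniform(1, 20, 12)
        ids = [f"s{i:02d}" for i in range(12)]
        c = self._cohort(list(wmh), ids)
        feats = rng.normal(0, 1, (12, 4))
        pts1 = build_pseudo_timeseries(feats, c, covariates=())
        perm = rng.permutation(12)
        pts2 = build_pseudo_timeseries(feats[perm],
                                       c.iloc[perm].reset_index(drop=True),
                                       covariates=())
        assert pts1.subject_ids == pts2.subject_ids
        np.testing.assert_allclose(pts1.data, pts2.data, atol=1e-12)

    def test_missing_wmh_rejected(self):
        c = self._cohort([1.0, np.nan, 2.0], ["a", "b", "c"])
        with pytest.raises(ValueError, match="WMH"):
            build_pseudo_timeseries(np.eye(3), c, covariates=())


class TestSeedSeries:
    def test_single_voxel_and_uniform_region(self, small_study):
        cohort, images, truth = small_study
        pts = build_pseudo_timeseries(images, cohort)
        single = np.zeros(images.mask.shape, dtype=bool)
        single[6, 12, 12] = True
        col = extract_seed_series(pts, single)
        np.testing.assert_allclose(
            col, pts.data[:, single[pts.mask]].ravel(), atol=1e-12)

    def test_planted_source_series_decreasing_noiseless(self):
        cfg = GeneratorConfig(voxel_noise_sd=0.0, smooth_fwhm_vox=0.0)
        cohort = generate_cohort(30, 0, cfg, seed=9)
        truth = default_ground_truth(cfg)
        images = generate_images(cohort, truth, cfg, seed=9)
        pts = build_pseudo_timeseries(images, cohort, covariates=())
        series = extract_seed_series(pts, truth.source)
        assert (np.diff(series) < 0).all()

    def test_empty_seed_intersection(self, small_study):
        cohort, images, _ = small_study
        pts = build_pseudo_timeseries(images, cohort)
        with pytest.raises(ValueError, match="intersect"):
            extract_seed_series(pts, np.zeros(images.mask.shape, dtype=bool))


class TestSignedGC:
    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            x = rng.normal(0, 1, 40)
            y = rng.normal(0, 1, 40)
            assert signed_gc_pair(x, y) == pytest.approx(gc_oracle(x, y),
                                                         abs=1e-10)

    def test_time_reversal_matches_oracle(self, rng):
        """Reversing both series and exchanging roles stays oracle-exact."""
        for _ in range(20):
            x = rng.normal(0, 1, 60)
            y = x + rng.normal(0, 0.5, 60)
            xr, yr = y[::-1], x[::-1]
            assert signed_gc_pair(xr, yr) == pytest.approx(
                gc_oracle(xr, yr), abs=1e-10)

    def test_null_white_noise_small(self, rng):
        x = rng.normal(0, 1, 2000)
        y = rng.normal(0, 1, 2000)
        assert abs(signed_gc_pair(x, y)) < 0.1

    def test_unit_lag_identifiability(self, rng):
        x = rng.normal(0, 1, 501)
        y = np.concatenate([[0.0], x[:-1]])
        assert signed_gc_pair(x[1:], y[1:]) == pytest.approx(1.0, abs=0.05)

    def test_preconditions(self, rng):
        with pytest.raises(ValueError):
            signed_gc_pair(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError, match="constant"):
            signed_gc_pair(rng.normal(0, 1, 20), np.full(20, 3.0))


class TestZScore:
    def test_moments_after_standardization(self, rng):
        mask = np.ones((6, 6, 6), dtype=bool)
        grid = rng.normal(2, 3, (6, 6, 6))
        m = zscore_map(GCMap(gc=grid, mask=mask, direction="seed_to_target"))
        assert m.z[mask].mean() == pytest.approx(0.0, abs=1e-10)
        assert m.z[mask].std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_two_voxel_convention(self):
        """Sample-sd (ddof=1) denominator: z = (−1, +1)/sqrt(2) for (a, b)."""
        mask = np.zeros((2, 1, 1), dtype=bool)
        mask[:, 0, 0] = True
        grid = np.zeros((2, 1, 1))
        grid[0, 0, 0], grid[1, 0, 0] = 1.0, 3.0
        m = zscore_map(GCMap(gc=grid, mask=mask, direction="seed_to_target"))
        np.testing.assert_allclose(m.z[mask], [-1 / np.sqrt(2), 1 / np.sqrt(2)],
                                   atol=1e-12)

    def test_constant_map_rejected(self):
        mask = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError, match="constant"):
            zscore_map(GCMap(gc=np.ones((3, 3, 3)), mask=mask,
                             direction="seed_to_target"))


class TestVoxelwise:
    def test_planted_signs(self, default_study):
        cohort, images, truth = default_study
        pts = build_pseudo_timeseries(images, cohort)
        ss = extract_seed_series(pts, truth.source)
        fwd, rev = voxelwise_cascn(pts, ss, seed=truth.source)
        shape = images.mask.shape
        a1 = truth.positive_targets[0].mask(shape)
        comp = truth.negative_targets[0].mask(shape)
        assert np.nanmean(fwd.gc[a1]) > 0.2
        assert np.nanmean(fwd.gc[comp]) < -0.2
        assert fwd.direction == "seed_to_target"
        assert rev.direction == "target_to_seed"

    def test_matches_pairwise_gc_spot_check(self, small_study):
        cohort, images, _ = small_study
        pts = build_pseudo_timeseries(images, cohort)
        ss = extract_seed_series(pts, Region("s", (6, 12, 12), 2))
        fwd, rev = voxelwise_cascn(pts, ss)
        flat_idx = np.flatnonzero(pts.mask.ravel())
        for vox in [17, 480, 2210]:
            i, j, k = np.unravel_index(flat_idx[vox], pts.mask.shape)
            assert fwd.gc[i, j, k] == pytest.approx(
                signed_gc_pair(ss, pts.data[:, vox]), abs=1e-10)
            assert rev.gc[i, j, k] == pytest.approx(
                signed_gc_pair(pts.data[:, vox], ss), abs=1e-10)

    def test_shuffled_ordering_null_calibration(self, default_study, rng):
        """Destroying the ordering leaves ~5% of voxels above |z| = 1.96."""
        cohort, images, truth = default_study
        pts = build_pseudo_timeseries(images, cohort)
        perm = rng.permutation(pts.n_time)
        pts.data = pts.data[perm]
        ss = extract_seed_series(pts, truth.source)
        fwd, _ = voxelwise_cascn(pts, ss)
        frac = np.mean(np.abs(fwd.z[images.mask]) > 1.96)
        assert 0.02 < frac < 0.09


class TestThreshold:
    def test_empty_when_nothing_passes(self, small_study):
        cohort, images, truth = small_study
        pts = build_pseudo_timeseries(images, cohort)
        ss = extract_seed_series(pts, truth.source)
        fwd, _ = voxelwise_cascn(pts, ss)
        strict = AnalysisConfig.desk_scale(z_threshold=50.0)
        out = threshold_cascn(fwd, pts, truth.source, strict, n_perm=100)
        assert len(out) == 0

    def test_planted_regions_recovered_with_signs(self, default_study):
        cohort, images, truth = default_study
        pts = build_pseudo_timeseries(images, cohort)
        ss = extract_seed_series(pts, truth.source)
        fwd, _ = voxelwise_cascn(pts, ss, seed=truth.source)
        out = threshold_cascn(fwd, pts, truth.source,
                              AnalysisConfig.desk_scale(), n_perm=100, seed=0)
        sig = out.significant()
        shape = images.mask.shape

        def covered(region, sign):
            rmask = region.mask(shape)
            return any(c.sign == sign and rmask[tuple(c.voxels.T)].any()
                       for c in sig)

        for tgt in truth.positive_targets:
            assert covered(tgt, +1), f"missed positive target {tgt.name}"
        for tgt in truth.negative_targets:
            assert covered(tgt, -1), f"missed negative target {tgt.name}"

    def test_insufficient_permutations(self, small_study):
        cohort, images, truth = small_study
        pts = build_pseudo_timeseries(images, cohort)
        ss = extract_seed_series(pts, truth.source)
        fwd, _ = voxelwise_cascn(pts, ss)
        with pytest.raises(ValueError, match="100"):
            threshold_cascn(fwd, pts, truth.source, n_perm=10)
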