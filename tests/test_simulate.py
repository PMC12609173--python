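"""Synthetic-cohort generator: calibration, construction identities, errors."""

import math

import numpy as np
import pandas as pd
import pytest

from cascnet.config import GeneratorConfig
from cascnet.simulate import (default_ground_truth, generate_cognition,
                              generate_cohort, generate_images,
                              region_atrophy_series, source_atrophy,
                              wmh_rank_order)
from cascnet.types import GroundTruth, Region


def noiseless_config(**kw):
    return GeneratorConfig(voxel_noise_sd=0.0, smooth_fwhm_vox=0.0, **kw)


class TestCohort:
    def test_seeded_determinism(self):
        a = generate_cohort(30, 8, seed=42)
        b = generate_cohort(30, 8, seed=42)
        pd.testing.assert_frame_equal(a, b)
        c = generate_cohort(30, 8, seed=43)
        assert not a["wmh_volume"].equals(c["wmh_volume"])

    def test_lognormal_parameters_from_quartiles(self):
        # solving the normal-quantile equations for the printed quartiles:
        # sigma = (ln 11.68 - ln 2.64) / (2 * 0.6745), mu = ln 5.24
        cfg = GeneratorConfig()
        assert cfg.wmh_mu == pytest.approx(math.log(5.24), abs=1e-12)
        assert cfg.wmh_sigma == pytest.approx(
            (math.log(11.68) - math.log(2.64)) / (2 * 0.6744897501960817),
            abs=1e-12)
        assert cfg.wmh_sigma == pytest.approx(1.102, abs=2e-3)
        assert cfg.wmh_mu == pytest.approx(1.656, abs=1e-3)

    def test_marginal_calibration_over_seeds(self):
        """Patient WMH median and quartiles within 10% of the targets."""
        meds, q1s, q3s = [], [], []
        for s in range(20):
            pat = generate_cohort(185, 0, seed=s)
            w = pat["wmh_volume"]
            meds.append(np.median(w))
            q1s.append(np.quantile(w, 0.25))
            q3s.append(np.quantile(w, 0.75))
        assert np.mean(meds) == pytest.approx(5.24, rel=0.10)
        assert np.mean(q1s) == pytest.approx(2.64, rel=0.10)
        assert np.mean(q3s) == pytest.approx(11.68, rel=0.10)

    def test_group_invariants(self):
        t = generate_cohort(25, 10, seed=0)
        pat = t[t.group == "patient"]
        ctl = t[t.group == "control"]
        assert (pat.fazekas >= 1).all() and (pat.wmh_volume > 0).all()
        assert (ctl.fazekas == 0).all() and (ctl.wmh_volume == 0).all()
        assert t.subject_id.is_unique

    def test_planted_gmv_correlation_is_exact(self):
        cfg = GeneratorConfig(wmh_gmv_r=-0.8)
        pat = generate_cohort(100, 0, cfg, seed=5)
        r = np.corrcoef(pat.wmh_volume, pat.global_gmv)[0, 1]
        assert r == pytest.approx(-0.8, abs=1e-10)

    def test_invalid_counts(self):
        with pytest.raises(ValueError):
            generate_cohort(3, 10, seed=0)
        with pytest.raises(ValueError):
            GeneratorConfig(wmh_q1=6.0)   # q1 above median


class TestImages:
    def test_source_monotone_without_noise(self):
        cfg = noiseless_config()
        cohort = generate_cohort(30, 0, cfg, seed=1)
        truth = default_ground_truth(cfg)
        images = generate_images(cohort, truth, cfg, seed=1)
        order = wmh_rank_order(cohort)
        smask = truth.source.mask(images.mask.shape)
        means = [images.data[i][smask].mean() for i in order]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_lagged_construction_identity(self):
        """Target atrophy = weight x source atrophy shifted by one rank."""
        cfg = noiseless_config()
        src = Region("source", (6, 12, 12), 2)
        tgt = Region("t", (16, 12, 12), 2, weight=0.8, lag=1)
        truth = GroundTruth(source=src, positive_targets=[tgt],
                            atrophy_slope=cfg.atrophy_slope)
        cohort = generate_cohort(20, 0, cfg, seed=2)
        images = generate_images(cohort, truth, cfg, seed=2)
        order = wmh_rank_order(cohort)
        wmh_sorted = cohort.wmh_volume.to_numpy()[order]
        src_atrophy = source_atrophy(wmh_sorted, cfg.atrophy_slope)
        tmask = tgt.mask(images.mask.shape)
        tgt_atrophy = np.array(
            [cfg.baseline_density - images.data[i][tmask].mean()
             for i in order])
        expected = np.concatenate([[0.0], 0.8 * src_atrophy[:-1]])
        np.testing.assert_allclose(tgt_atrophy, expected, atol=1e-12)

    def test_negative_target_gains_density(self):
        cfg = noiseless_config()
        truth = GroundTruth(
            source=Region("source", (6, 12, 12), 2),
            negative_targets=[Region("n", (16, 12, 12), 2, weight=-0.5, lag=1)],
            atrophy_slope=cfg.atrophy_slope)
        cohort = generate_cohort(20, 0, cfg, seed=3)
        images = generate_images(cohort, truth, cfg, seed=3)
        nmask = truth.negative_targets[0].mask(images.mask.shape)
        last = wmh_rank_order(cohort)[-1]
        assert images.data[last][nmask].mean() > cfg.baseline_density

    def test_chained_parent_composes_lag_and_weight(self):
        src = Region("source", (6, 12, 12), 2)
        a = Region("a", (12, 6, 12), 2, weight=0.5, lag=1, parent="source")
        b = Region("b", (18, 6, 12), 2, weight=0.5, lag=2, parent="a")
        truth = GroundTruth(source=src, positive_targets=[a, b],
                            atrophy_slope=0.06)
        wmh = np.linspace(1, 20, 12)
        series = region_atrophy_series(truth, wmh)
        expected = np.zeros(12)
        expected[3:] = 0.25 * series["source"][:-3]
        np.testing.assert_allclose(series["b"], expected, atol=1e-15)

    def test_rejects_overlap_and_long_lag(self):
        cfg = noiseless_config()
        cohort = generate_cohort(10, 0, cfg, seed=0)
        overlap = GroundTruth(
            source=Region("source", (6, 12, 12), 2),
            positive_targets=[Region("t", (7, 12, 12), 2, weight=1, lag=1)])
        with pytest.raises(ValueError, match="overlap"):
            generate_images(cohort, overlap, cfg, seed=0)
        long_lag = GroundTruth(
            source=Region("source", (6, 12, 12), 2),
            positive_targets=[Region("t", (16, 12, 12), 2, weight=1, lag=10)])
        with pytest.raises(ValueError, match="lag"):
            generate_images(cohort, long_lag, cfg, seed=0)

    def test_controls_unlesioned(self):
        cfg = noiseless_config()
        cohort = generate_cohort(10, 5, cfg, seed=4)
        truth = default_ground_truth(cfg)
        images = generate_images(cohort, truth, cfg, seed=4)
        ctl_rows = np.flatnonzero((cohort.group == "control").to_numpy())
        for i in ctl_rows:
            np.testing.assert_allclose(images.data[i], cfg.baseline_density)


class TestCognition:
    def test_pure_direct_effect_reproduces_wmh(self):
        """noise 0, b = 0, c' = 1: the standardized score is z(WMH)."""
        cfg = GeneratorConfig(dst_b=0.0, dst_c_prime=1.0,
                              cognition_noise_sd=0.0)
        cohort = generate_cohort(50, 0, cfg, seed=6)
        out = generate_cognition(cohort, cfg, seed=6)
        w = out.wmh_volume.to_numpy()
        d = out.dst.to_numpy()
        zw = (w - w.mean()) / w.std()
        zd = (d - d.mean()) / d.std()
        np.testing.assert_allclose(zd, zw, atol=1e-10)

    def test_patient_score_scale_matches_calibration(self):
        cfg = GeneratorConfig()
        cohort = generate_cohort(185, 40, cfg, seed=7)
        out = generate_cognition(cohort, cfg, seed=7)
        pat = out[out.group == "patient"]
        assert pat.dst.mean() == pytest.approx(50.63, abs=1e-8)
        assert pat.dst.to_numpy().std() == pytest.approx(18.28, rel=1e-6)
        assert (pat.tmt_a > 0).all()

    def test_requires_gmv(self):
        cohort = generate_cohort(10, 0, seed=0)
        cohort["global_gmv"] = np.nan
        with pytest.raises(ValueError, match="global_gmv"):
            generate_cognition(cohort, seed=0)
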