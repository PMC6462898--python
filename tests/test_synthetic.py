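"""Synthetic generator: determinism, programmed structure, corruption."""

import dataclasses

import numpy as np
import pytest

from patcorr.correlation import pearson
from patcorr.quality import screen_record
from patcorr.synthetic import (
    CohortConfig,
    SyntheticConfig,
    corrupt_record,
    generate_bp_series,
    generate_cohort,
    generate_record,
)


class TestBPSeries:
    def test_zero_variance_process_is_constant(self):
        cfg = SyntheticConfig(n_beats=50, sbp_sd=0.0, seed=4)
        sbp, dbp, _ = generate_bp_series(cfg)
        assert np.all(sbp == cfg.sbp_mean)
        assert np.all(dbp < sbp)

    def test_determinism(self):
        cfg = SyntheticConfig(n_beats=200, seed=11)
        a = generate_bp_series(cfg)
        b = generate_bp_series(cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_sample_mean_within_autocorrelated_tolerance(self):
        # AR(1) with lag-1 phi inflates the SE of the mean by
        # c = sqrt((1+phi)/(1-phi)) ~ 4.36 at phi = 0.9 (Monte-Carlo over
        # 300 seeds gave c_hat = 4.08, max deviation 5.70)
        c = np.sqrt(1.9 / 0.1)
        tol = 3.0 * (10.0 / np.sqrt(500)) * c
        for seed in range(5):
            cfg = SyntheticConfig(n_beats=500, sbp_mean=120.0, sbp_sd=10.0, seed=seed)
            sbp, _, _ = generate_bp_series(cfg)
            assert abs(sbp.mean() - 120.0) < tol

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="n_beats"):
            generate_bp_series(SyntheticConfig(n_beats=0))
        with pytest.raises(ValueError, match="fraction"):
            generate_bp_series(SyntheticConfig(pat_rsstar_fraction=1.0))
        with pytest.raises(ValueError, match="sbp_sd"):
            generate_bp_series(SyntheticConfig(sbp_sd=-1.0))


class TestGenerateRecord:
    def test_construction_counts_and_duration(self):
        cfg = SyntheticConfig(n_beats=10, hr_mean=60.0, hr_sd=0.0, fs=125.0, seed=0)
        rec, gt = generate_record(cfg)
        assert gt.n_beats == 10
        assert 10.0 <= rec.duration <= 12.5  # 10 s of beats plus lead-in/out
        assert rec.fs == 125.0
        assert len(rec.ecg) == len(rec.ppg) == len(rec.abp)

    def test_bit_identical_under_same_config(self):
        cfg = SyntheticConfig(n_beats=20, seed=9)
        r1, g1 = generate_record(cfg)
        r2, g2 = generate_record(cfg)
        for c in ("ecg", "ppg", "abp"):
            np.testing.assert_array_equal(getattr(r1, c), getattr(r2, c))
        np.testing.assert_array_equal(g1.s_time, g2.s_time)

    def test_constant_delay_when_uncoupled(self):
        cfg = SyntheticConfig(n_beats=30, coupling_slope=0.0, pat_noise_sd=0.0, seed=2)
        _, gt = generate_record(cfg)
        np.testing.assert_allclose(gt.pat_rs, cfg.pat_rs_mean, atol=1e-12)

    def test_programmed_negative_coupling_visible_in_truth(self):
        cfg = SyntheticConfig(
            n_beats=500, coupling_slope=-0.002, pat_noise_sd=0.002, seed=5
        )
        _, gt = generate_record(cfg)
        assert pearson(gt.pat_rs, gt.sbp) < -0.9

    def test_ground_truth_ordering_invariants(self, clean_record):
        _, gt = clean_record
        assert np.all(np.diff(gt.r_time) > 0)
        assert np.all(gt.r_time < gt.o_time)
        assert np.all(gt.o_time <= gt.a_time)
        assert np.all(gt.a_time <= gt.w_time)
        assert np.all(gt.w_time <= gt.b_time)
        assert np.all(gt.b_time <= gt.s_time)
        assert np.all((gt.sstar_time > gt.r_time) & (gt.sstar_time < gt.s_time))
        assert np.all(gt.dstar_time > gt.sstar_time)
        assert np.all((gt.dbp < gt.map) & (gt.map < gt.sbp))

    def test_additive_split_is_exact(self, clean_record):
        _, gt = clean_record
        np.testing.assert_array_equal(
            gt.s_time - gt.r_time,
            (gt.sstar_time - gt.r_time) + (gt.s_time - gt.sstar_time),
        )

    def test_programmed_correlation_matches_analytic_value(self):
        # r = slope*sd / sqrt(slope^2 sd^2 + noise^2) = -0.8 for these values
        slope, sd, noise = -0.002, 10.0, 0.015
        analytic = slope * sd / np.hypot(slope * sd, noise)
        rs = []
        for seed in range(20):
            cfg = SyntheticConfig(
                n_beats=2000, coupling_slope=slope, sbp_sd=sd, pat_noise_sd=noise, seed=seed
            )
            _, gt = generate_record(cfg)
            rs.append(pearson(gt.pat_rs, gt.sbp))
        assert abs(float(np.mean(rs)) - analytic) < 0.05

    def test_impossible_pat_rejected(self):
        with pytest.raises(ValueError, match="PAT"):
            generate_record(SyntheticConfig(n_beats=5, pat_rs_mean=2.0, hr_mean=80.0))
        with pytest.raises(ValueError, match="PAT"):
            generate_record(
                SyntheticConfig(n_beats=5, pat_rs_mean=0.01, pat_noise_sd=0.05, seed=1)
            )


class TestCorruption:
    def test_missing_modes_flatline_named_channel(self, clean_record):
        rec, _ = clean_record
        bad = corrupt_record(rec, "missing_abp", seed=0)
        assert np.ptp(bad.abp) == 0.0
        np.testing.assert_array_equal(bad.ecg, rec.ecg)
        np.testing.assert_array_equal(bad.ppg, rec.ppg)

    def test_good_mode_rejected(self, clean_record):
        rec, _ = clean_record
        with pytest.raises(ValueError, match="mode"):
            corrupt_record(rec, "good")

    def test_deterministic_given_seed(self, clean_record):
        rec, _ = clean_record
        a = corrupt_record(rec, "abnormal_ecg", seed=42)
        b = corrupt_record(rec, "abnormal_ecg", seed=42)
        np.testing.assert_array_equal(a.ecg, b.ecg)

    def test_abnormal_ppg_degrades_only_ppg_quality(self, clean_record):
        rec, _ = clean_record
        from patcorr.quality import _template_sqi

        bad = corrupt_record(rec, "abnormal_ppg", seed=3)
        assert _template_sqi(bad.ppg, rec.fs) < 0.8
        assert _template_sqi(bad.ecg, rec.fs) == _template_sqi(rec.ecg, rec.fs)

    @pytest.mark.parametrize(
        "mode",
        ["missing_abp", "missing_ecg", "missing_ppg", "abnormal_abp", "abnormal_ecg", "abnormal_ppg"],
    )
    def test_screening_roundtrip(self, clean_record, mode):
        rec, _ = clean_record
        assert screen_record(corrupt_record(rec, mode, seed=7)).category == mode


class TestCohort:
    def test_cohort_ids_and_determinism(self):
        cc = CohortConfig(
            n_subjects=3, base=SyntheticConfig(n_beats=12), seed=8
        )
        a = generate_cohort(cc)
        b = generate_cohort(cc)
        assert [r.subject_id for r, _ in a] == ["subj000", "subj001", "subj002"]
        np.testing.assert_array_equal(a[1][0].ppg, b[1][0].ppg)

    def test_subjects_differ(self):
        cc = CohortConfig(n_subjects=2, base=SyntheticConfig(n_beats=12), seed=8)
        (r1, g1), (r2, g2) = generate_cohort(cc)
        assert not np.array_equal(r1.ecg[: len(r2.ecg)], r2.ecg[: len(r1.ecg)])
        assert g1.sbp.mean() != g2.sbp.mean()
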