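"""Pearson engine, strength bins, and the three analysis modes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patcorr.correlation import (
    ZeroVarianceError,
    analyze_collective,
    analyze_one_excellent_beat,
    analyze_subject_by_subject,
    pearson,
    render_reports,
    select_excellent_beats,
    strength_bin,
    CorrelationReport,
)
from patcorr.features import build_feature_table
from patcorr.synthetic import CohortConfig, SyntheticConfig, generate_cohort
from conftest import brute_force_pearson


def _cohort_table(n_subjects, n_beats, seed=0, **synth_kw):
    base = SyntheticConfig(n_beats=n_beats, **synth_kw)
    cohort = generate_cohort(CohortConfig(n_subjects=n_subjects, base=base, seed=seed))
    return build_feature_table([rec for rec, _ in cohort])


class TestPearson:
    def test_perfect_linear(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_known_value_vs_brute_force(self):
        x, y = [1, 2, 3, 4], [1, 3, 2, 4]
        assert brute_force_pearson(x, y) == pytest.approx(0.8)
        assert pearson(x, y) == pytest.approx(0.8, abs=1e-15)

    def test_zero_variance_signalled(self):
        with pytest.raises(ZeroVarianceError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            pearson([1.0], [2.0])
        with pytest.raises(ValueError):
            pearson([1.0, np.nan], [2.0, 3.0])

    def test_oracle_equivalence_1000_random_arrays(self):
        """Engine matches the explicit-sum oracle to 1e-12 everywhere."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(2, 101))
            x = rng.normal(scale=rng.uniform(0.1, 50), size=n)
            y = rng.normal(scale=rng.uniform(0.1, 50), size=n) + rng.uniform(-1, 1) * x
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            assert abs(pearson(x, y) - brute_force_pearson(x, y)) < 1e-12

    @given(
        st.integers(2, 60),
        st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3),
        st.floats(-100, 100),
        st.integers(0, 2**16),
    )
    @settings(max_examples=60, deadline=None)
    def test_affine_invariance_and_symmetry(self, n, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        if np.std(x) == 0 or np.std(y) == 0:
            return
        r = pearson(x, y)
        assert pearson(y, x) == pytest.approx(r, abs=1e-12)
        assert pearson(a * x + b, y) == pytest.approx(np.sign(a) * r, abs=1e-12)


class TestStrengthBin:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (-0.92, "very strong"),
            (-0.07, "very weak"),
            (0.0, "very weak"),
            (0.2, "weak"),
            (0.4, "moderate"),
            (0.6, "strong"),
            (0.8, "very strong"),
            (0.795, "strong"),
            (1.0, "very strong"),
            (-1.0, "very strong"),
        ],
    )
    def test_bins(self, r, expected):
        assert strength_bin(r) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            strength_bin(1.2)


class TestSubjectBySubject:
    def test_strong_programmed_coupling_all_very_strong(self):
        table = _cohort_table(4, 80, seed=1, coupling_slope=-0.002, pat_noise_sd=0.002)
        report = analyze_subject_by_subject(table, bin_feature="pat_rs")
        assert len(report.rows) == 4
        assert (report.rows["r_pat_rs"] < -0.8).all()
        assert report.strength_bins["very strong"] == 4
        assert sum(report.strength_bins.values()) == 4

    def test_null_coupling_mean_near_zero(self):
        table = _cohort_table(6, 100, seed=2, coupling_slope=0.0)
        report = analyze_subject_by_subject(table)
        mean_r = report.rows["r_pat_rs"].mean()
        se = 1.0 / np.sqrt(100) / np.sqrt(6)
        assert abs(mean_r) < 2 * se + 0.02

    def test_single_subject_summary(self):
        table = _cohort_table(1, 30, seed=3)
        report = analyze_subject_by_subject(table)
        assert len(report.rows) == 1
        mean, sd = report.summary.iloc[0], report.summary.iloc[1]
        for col in report.rows.columns:
            if col.startswith("r_"):
                assert mean[col] == pytest.approx(report.rows[col].iloc[0])
                assert sd[col] == 0.0

    def test_subject_with_one_beat_skipped(self):
        table = _cohort_table(2, 30, seed=4)
        lone = table.iloc[[0]].assign(subject_id="lonely")
        report = analyze_subject_by_subject(pd.concat([table, lone], ignore_index=True))
        assert "lonely" not in set(report.rows["subject_id"])


class TestCollective:
    def test_pooled_equals_single_subject_table(self):
        table = _cohort_table(1, 60, seed=5)
        pooled = analyze_collective(table, "sbp")
        subj = analyze_subject_by_subject(table)
        for feat in ("pat_rs", "pat_ro", "rri"):
            assert pooled.rows[f"r_{feat}"].iloc[0] == pytest.approx(
                subj.rows[f"r_{feat}"].iloc[0]
            )

    def test_pooling_is_not_averaging(self):
        """Opposite within-subject slopes can invert under pooling."""
        table = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b", "b"],
                "sbp": [1.0, 0.0, 11.0, 10.0],
                "pat_rs": [0.0, 1.0, 10.0, 11.0],
            }
        )
        within_a = pearson(table[table.subject_id == "a"].sbp, table[table.subject_id == "a"].pat_rs)
        within_b = pearson(table[table.subject_id == "b"].sbp, table[table.subject_id == "b"].pat_rs)
        pooled = pearson(table.sbp, table.pat_rs)
        assert within_a == within_b == pytest.approx(-1.0)
        assert pooled > 0.9

    def test_bp_target_validation(self):
        table = _cohort_table(1, 20, seed=6)
        with pytest.raises(ValueError, match="bp_target"):
            analyze_collective(table, "pulse")
        with pytest.raises(ValueError, match="empty"):
            analyze_collective(table.iloc[0:0], "sbp")

    def test_map_and_dbp_targets_run(self):
        table = _cohort_table(2, 40, seed=7)
        for bp in ("sbp", "map", "dbp"):
            rows = analyze_collective(table, bp).rows
            assert rows["n_beats"].iloc[0] == len(table)
            assert rows["bp_target"].iloc[0] == bp.upper()


class TestOneExcellentBeat:
    def test_one_row_per_subject(self):
        table = _cohort_table(5, 30, seed=8)
        report = analyze_one_excellent_beat(table)
        assert report.rows["n_beats"].iloc[0] == 5
        assert report.mode == "one_excellent_beat"

    def test_tie_breaks_to_first_beat(self):
        table = pd.DataFrame(
            {
                "subject_id": ["a"] * 3,
                "beat_index": [4, 5, 6],
                "quality": [0.9, 0.9, 0.9],
                "sbp": [1.0, 2.0, 3.0],
            }
        )
        best = select_excellent_beats(table)
        assert best["beat_index"].iloc[0] == 4

    def test_selection_only_from_extracted_beats(self):
        table = _cohort_table(3, 25, seed=9)
        best = select_excellent_beats(table)
        merged = best.merge(table, on=["subject_id", "beat_index"], how="left")
        assert not merged["pat_rs_y"].isna().any()


class TestRenderReports:
    def test_subject_mode_files_and_footer(self, tmp_path):
        table = _cohort_table(3, 25, seed=10)
        report = analyze_subject_by_subject(table)
        paths = render_reports(report, tmp_path, header="h123")
        per_subject = next(p for p in paths if "per_subject" in p.name)
        text = per_subject.read_text()
        assert text.startswith("#h123")
        assert "Mean ± STD" in text
        bins_path = next(p for p in paths if "strength_bins" in p.name)
        bins = pd.read_csv(bins_path, comment="#")
        assert bins["n_subjects"].sum() == 3

    def test_rounding_to_two_decimals(self, tmp_path):
        table = _cohort_table(2, 25, seed=11)
        report = analyze_collective(table, "sbp")
        (path,) = render_reports(report, tmp_path)
        back = pd.read_csv(path, comment="#")
        r = back["r_pat_rs"].iloc[0]
        assert r == round(r, 2)

    def test_empty_report_header_only(self, tmp_path):
        empty = CorrelationReport(mode="collective", rows=pd.DataFrame(columns=["bp_target", "n_beats"]))
        (path,) = render_reports(empty, tmp_path)
        back = pd.read_csv(path)
        assert back.empty and list(back.columns) == ["bp_target", "n_beats"]
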