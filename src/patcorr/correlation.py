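"""Pearson correlation engine, strength binning, and the three analyses.

Three complementary views of the PAT–BP relationship:

* subject-by-subject — r between SBP and each propagation feature within
  each subject, summarized by an unweighted mean ± SD across subjects and
  by strength-bin counts on one configured feature;
* collective — r over all beats of all subjects pooled, for a chosen BP
  target (SBP, MAP or DBP), with no per-subject centering (so
  between-subject offsets contribute: pooling is not averaging);
* one excellent beat — r across subjects using each subject's single
  highest-SQI beat.

The correlation itself is the standard sample Pearson coefficient
r = cov(x, y) / (sd_x * sd_y). (The printed source formula for r carries
an obvious sign typo in its denominator; the standard form is what the
surrounding text and the cited literature intend.)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import BP_COLUMNS, FEATURE_COLUMNS

#: Strength bins on |r|, half-open below the top so every |r| in [0, 1]
#: falls in exactly one bin (0.795 is "strong"; 0.8 is "very strong").
STRENGTH_BINS = (
    ("very weak", 0.0, 0.2),
    ("weak", 0.2, 0.4),
    ("moderate", 0.4, 0.6),
    ("strong", 0.6, 0.8),
    ("very strong", 0.8, 1.0 + 1e-12),
)

#: Feature on which subject-mode strength bins are counted (the feature
#: with the highest overall SBP correlation in the reference analysis).
DEFAULT_BIN_FEATURE = "pat_rsstar"


class ZeroVarianceError(ValueError):
    """Pearson r is undefined when either argument has zero variance."""


def pearson(x, y) -> float:
    """Standard sample Pearson correlation coefficient.

    Raises :class:`ZeroVarianceError` rather than silently returning 0
    when either input is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0.0 or sy == 0.0:
        raise ZeroVarianceError("Pearson r undefined for zero-variance input")
    return float(np.sum(xc * yc) / (sx * sy))


def strength_bin(r: float) -> str:
    """Strength category of a correlation coefficient, binned on |r|."""
    a = abs(float(r))
    if a > 1.0 + 1e-12:
        raise ValueError(f"|r| must be <= 1, got {r}")
    for name, lo, hi in STRENGTH_BINS:
        if lo <= a < hi:
            return name
    raise AssertionError("unreachable")


@dataclass
class CorrelationReport:
    """Result container shared by the three analysis modes.

    ``rows`` has one row per subject (subject mode) or per BP target
    (pooled modes), with one column per feature plus ``n_beats``.
    ``summary`` and ``strength_bins`` are filled in subject mode only.
    """

    mode: str
    rows: pd.DataFrame
    summary: pd.DataFrame | None = None
    strength_bins: dict[str, int] = field(default_factory=dict)
    bin_feature: str = DEFAULT_BIN_FEATURE


def _safe_r(x, y) -> float:
    try:
        return pearson(x, y)
    except ZeroVarianceError:
        return np.nan


def analyze_subject_by_subject(
    table: pd.DataFrame, bin_feature: str = DEFAULT_BIN_FEATURE
) -> CorrelationReport:
    """Within-subject r between SBP and each feature, plus bin counts.

    Subjects with fewer than 2 beats are skipped. The summary row is the
    unweighted mean ± SD of per-subject coefficients; bin counts are on
    ``bin_feature`` and sum to the number of analyzed subjects.
    """
    if bin_feature not in FEATURE_COLUMNS:
        raise ValueError(f"unknown bin feature {bin_feature!r}")
    rows = []
    for sid, grp in table.groupby("subject_id", sort=True):
        if len(grp) < 2:
            continue
        row = {"subject_id": sid, "n_beats": len(grp)}
        for feat in FEATURE_COLUMNS:
            row[f"r_{feat}"] = _safe_r(grp["sbp"], grp[feat])
        rows.append(row)
    rows_df = pd.DataFrame(rows, columns=["subject_id", "n_beats"] + [f"r_{f}" for f in FEATURE_COLUMNS])
    rcols = [f"r_{f}" for f in FEATURE_COLUMNS]
    summary = pd.DataFrame(
        {
            "statistic": ["mean", "std"],
            **{
                c: [rows_df[c].mean(), rows_df[c].std(ddof=0) if len(rows_df) else np.nan]
                for c in rcols
            },
        }
    )
    bins = {name: 0 for name, _, _ in STRENGTH_BINS}
    for r in rows_df[f"r_{bin_feature}"].dropna():
        bins[strength_bin(r)] += 1
    return CorrelationReport(
        mode="subject_by_subject",
        rows=rows_df,
        summary=summary,
        strength_bins=bins,
        bin_feature=bin_feature,
    )


def analyze_collective(table: pd.DataFrame, bp_target: str = "sbp") -> CorrelationReport:
    """Pooled r over all beats between one BP column and each feature."""
    bp = bp_target.lower()
    if bp not in BP_COLUMNS:
        raise ValueError(f"bp_target must be one of {BP_COLUMNS}, got {bp_target!r}")
    if table.empty:
        raise ValueError("feature table is empty")
    row = {"bp_target": bp.upper(), "n_beats": len(table)}
    for feat in FEATURE_COLUMNS:
        row[f"r_{feat}"] = _safe_r(table[bp], table[feat])
    return CorrelationReport(mode="collective", rows=pd.DataFrame([row]))


def select_excellent_beats(table: pd.DataFrame) -> pd.DataFrame:
    """One row per subject: the beat with the highest quality score.

    Ties (and missing quality scores) resolve to the earliest beat.
    """
    if "quality" not in table.columns:
        raise ValueError("feature table has no 'quality' column")
    picks = []
    for _, grp in table.groupby("subject_id", sort=True):
        q = grp["quality"].fillna(-np.inf).to_numpy()
        picks.append(grp.iloc[int(np.argmax(q))])
    return pd.DataFrame(picks).reset_index(drop=True)


def analyze_one_excellent_beat(table: pd.DataFrame, bp_target: str = "sbp") -> CorrelationReport:
    """r across subjects using each subject's single best-quality beat."""
    best = select_excellent_beats(table)
    report = analyze_collective(best, bp_target=bp_target)
    report.mode = "one_excellent_beat"
    return report


def render_reports(report: CorrelationReport, out_dir, prefix: str = "", header: str = "") -> list:
    """Write delimited report tables with r rounded to 2 decimals.

    Subject mode writes a per-subject table (with a ``Mean ± STD`` footer
    row) and a strength-bin table; pooled modes write one table.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rcols = [c for c in report.rows.columns if c.startswith("r_")]
    written = []

    def _write(df: pd.DataFrame, name: str):
        path = out_dir / f"{prefix}{name}.csv"
        with open(path, "w", newline="") as f:
            if header:
                f.write(f"#{header}\n")
            df.to_csv(f, index=False)
        written.append(path)

    rows = report.rows.copy()
    rows[rcols] = rows[rcols].round(2)
    if report.mode == "subject_by_subject":
        assert report.summary is not None
        mean, sd = report.summary.iloc[0], report.summary.iloc[1]
        footer = {"subject_id": "Mean ± STD", "n_beats": rows["n_beats"].mean().round(0) if len(rows) else np.nan}
        for c in rcols:
            footer[c] = f"{mean[c]:.2f} ± {sd[c]:.2f}" if np.isfinite(mean[c]) else ""
        rows = pd.concat([rows, pd.DataFrame([footer])], ignore_index=True)
        _write(rows, "per_subject")
        bins_df = pd.DataFrame(
            [
                {"strength": name, "abs_r_range": f"{lo:.1f}-{min(hi, 1.0):.2f}", "n_subjects": report.strength_bins[name]}
                for name, lo, hi in reversed(STRENGTH_BINS)
            ]
        )
        _write(bins_df, f"strength_bins_{report.bin_feature}")
    else:
        _write(rows, report.mode)
    return written
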