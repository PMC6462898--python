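#!/usr/bin/env python
"""Run the three PAT–BP correlation analyses and render the report tables.

From results/cohort/features.csv, computes (i) per-subject Pearson r
between SBP and each propagation feature with the strength-bin summary,
(ii) the pooled "collective beats" correlations against SBP, MAP and DBP,
and (iii) the one-excellent-beat-per-subject correlations. Writes the
delimited report tables under results/cohort/ and prints the pooled SBP
row. Because every simulated subject shares the same negative programmed
PAT–SBP coupling, within-subject correlations are strong while pooling
across subjects dilutes them through between-subject offsets — the
qualitative pattern these analyses exist to expose.

Run after 03_extract_features.py:  python analysis/04_correlate.py
"""

from pathlib import Path

import pandas as pd

from patcorr.correlation import (
    CorrelationReport,
    analyze_collective,
    analyze_one_excellent_beat,
    analyze_subject_by_subject,
    render_reports,
)
from patcorr.features import read_feature_table

OUT = Path("results/cohort")


def main() -> None:
    table = read_feature_table(OUT / "features.csv")

    subj = analyze_subject_by_subject(table)
    render_reports(subj, OUT)
    mean_r = subj.summary.iloc[0]["r_pat_rs"]
    sd_r = subj.summary.iloc[1]["r_pat_rs"]
    print(
        f"subject-by-subject: {len(subj.rows)} subjects, "
        f"r(SBP, PAT_RS) = {mean_r:.2f} ± {sd_r:.2f} (mean ± SD)"
    )
    print(f"  strength bins on PAT_RS*: {subj.strength_bins}")

    coll_rows, exc_rows = [], []
    for bp in ("sbp", "map", "dbp"):
        coll_rows.append(analyze_collective(table, bp_target=bp).rows)
        exc_rows.append(analyze_one_excellent_beat(table, bp_target=bp).rows)
    coll = CorrelationReport(mode="collective", rows=pd.concat(coll_rows, ignore_index=True))
    exc = CorrelationReport(
        mode="one_excellent_beat", rows=pd.concat(exc_rows, ignore_index=True)
    )
    render_reports(coll, OUT)
    render_reports(exc, OUT)

    sbp_row = coll.rows[coll.rows["bp_target"] == "SBP"].iloc[0]
    print(
        f"collective ({int(sbp_row['n_beats'])} beats): "
        + ", ".join(f"r(SBP, {f}) = {sbp_row[f'r_{f}']:.2f}" for f in ("pat_rs", "pat_rb", "pat_rsstar"))
    )
    exc_row = exc.rows[exc.rows["bp_target"] == "SBP"].iloc[0]
    print(
        f"one excellent beat ({int(exc_row['n_beats'])} subjects): "
        f"r(SBP, PAT_RS) = {exc_row['r_pat_rs']:.2f}"
    )
    print(f"report tables -> {OUT}")


if __name__ == "__main__":
    main()
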