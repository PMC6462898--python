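#!/usr/bin/env python
"""Extract the per-beat feature table from the screened records.

Filters each good record, detects the eight fiducials per beat, and
measures the seven PAT/PTT intervals, the R-R interval and the reference
SBP/MAP/DBP. Writes results/cohort/features.csv and prints the per-subject
beat bookkeeping (the "#PATs" column of the per-subject report).

Run after 02_screen_records.py:  python analysis/03_extract_features.py
"""

from pathlib import Path

from patcorr.features import build_feature_table, write_feature_table
from patcorr.pipeline import load_records_dir
from patcorr.quality import screen_cohort

OUT = Path("results/cohort")


def main() -> None:
    records = load_records_dir(OUT / "records")
    _, good = screen_cohort(records)
    table = build_feature_table(good)
    write_feature_table(table, OUT / "features.csv")

    per_subject = table.groupby("subject_id").size()
    print(
        f"extracted {len(table)} beats from {len(per_subject)} subjects "
        f"(#PATs per subject: min {per_subject.min()}, "
        f"median {int(per_subject.median())}, max {per_subject.max()})"
    )
    print(f"feature table -> {OUT / 'features.csv'}")


if __name__ == "__main__":
    main()
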