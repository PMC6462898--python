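#!/usr/bin/env python
"""Screen the simulated cohort into the seven quality categories.

Applies the automated missing/abnormal screening rules to every record in
results/cohort/records/, writes the resulting ledger, and prints the
per-category bookkeeping table alongside the packaged screening fixture's
published totals for comparison of the format (the fixture describes the
original 578-record MIMIC screen, not this simulation).

Run after 01_simulate_cohort.py:  python analysis/02_screen_records.py
"""

from pathlib import Path

from patcorr.pipeline import load_records_dir
from patcorr.quality import screen_cohort
from patcorr.records import load_table1_fixture, tabulate_ledger, write_ledger

OUT = Path("results/cohort")


def main() -> None:
    records = load_records_dir(OUT / "records")
    ledger, good = screen_cohort(records)
    write_ledger(ledger, OUT / "screening_ledger.csv")

    counts = tabulate_ledger(ledger)
    print(f"screened {counts['total']} records -> {len(good)} good")
    for cat, n in counts.items():
        if cat != "total":
            print(f"  {cat:>13}: {n}")

    ref = tabulate_ledger(load_table1_fixture())
    print(
        f"\npackaged screening fixture (original study bookkeeping): "
        f"{ref['total']} downloaded, {ref['good']} included, "
        f"{ref['missing_abp']} missing-ABP, {ref['missing_ppg']} missing-PPG"
    )


if __name__ == "__main__":
    main()
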