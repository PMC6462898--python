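#!/usr/bin/env python
"""Simulate the study cohort: 121 clean subjects plus 12 corrupted records.

Emulates the scale of the archived dataset the correlation analyses were
run on — 121 included subjects with on the order of 110 extracted beats
each — plus two corrupted records per failure mode so the screening stage
has something to reject. Writes the records (and per-beat ground truth
for the clean ones) under results/cohort/records/.

Run from the repository root:  python analysis/01_simulate_cohort.py [--seed N]
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from patcorr.pipeline import RunConfig, simulate_cohort
from patcorr.records import write_record
from patcorr.synthetic import SyntheticConfig

OUT = Path("results/cohort")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-subjects", type=int, default=121)
    ap.add_argument("--n-beats", type=int, default=111)
    args = ap.parse_args()

    cfg = RunConfig(
        out_dir=str(OUT),
        n_subjects=args.n_subjects,
        synthetic=SyntheticConfig(n_beats=args.n_beats, seed=args.seed),
        corrupt={
            "missing_abp": 2,
            "missing_ecg": 2,
            "missing_ppg": 2,
            "abnormal_abp": 2,
            "abnormal_ecg": 2,
            "abnormal_ppg": 2,
        },
        seed=args.seed,
    )
    rec_dir = OUT / "records"
    rec_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(OUT / "config.yaml")

    cohort = simulate_cohort(cfg)
    n_clean = 0
    for rec, gt in cohort:
        write_record(rec, rec_dir / f"{rec.subject_id}.csv")
        if gt is not None:
            pd.DataFrame(dataclasses.asdict(gt)).to_csv(
                rec_dir / f"{rec.subject_id}.truth.csv", index=False
            )
            n_clean += 1
    print(
        f"wrote {len(cohort)} records ({n_clean} clean subjects, "
        f"{len(cohort) - n_clean} corrupted) to {rec_dir}"
    )
    print(f"config hash {cfg.config_hash}, seed {args.seed}")


if __name__ == "__main__":
    main()
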