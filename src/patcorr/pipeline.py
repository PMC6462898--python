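"""End-to-end pipeline: simulate → screen → extract → correlate.

A :class:`RunConfig` fully determines a run; its SHA-1 hash is stamped
into every output header so any artifact can be traced to the exact
configuration and seed that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import correlation, features, quality, synthetic
from .records import WaveformRecord, read_record, write_ledger, write_record

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str = "patcorr_run"
    n_subjects: int = 20
    synthetic: synthetic.SyntheticConfig = field(default_factory=synthetic.SyntheticConfig)
    #: mapping corruption mode -> number of additional corrupted subjects
    corrupt: dict[str, int] = field(default_factory=dict)
    map_rule: str = "waveform_mean"
    bin_feature: str = correlation.DEFAULT_BIN_FEATURE
    bp_targets: tuple[str, ...] = ("sbp", "map", "dbp")
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["bp_targets"] = list(d["bp_targets"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and isinstance(d["synthetic"], dict):
            d["synthetic"] = synthetic.SyntheticConfig(**d["synthetic"])
        if "bp_targets" in d:
            d["bp_targets"] = tuple(d["bp_targets"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)

    @property
    def config_hash(self) -> str:
        # out_dir is a filesystem detail, not part of the scientific config
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def simulate_cohort(config: RunConfig) -> list[tuple[WaveformRecord, synthetic.GroundTruth | None]]:
    """Simulated cohort: clean subjects plus any configured corrupted ones."""
    base = dataclasses.replace(config.synthetic, seed=config.seed)
    cohort = synthetic.generate_cohort(
        synthetic.CohortConfig(n_subjects=config.n_subjects, base=base, seed=config.seed)
    )
    out: list[tuple[WaveformRecord, synthetic.GroundTruth | None]] = list(cohort)
    k = 0
    for mode, count in sorted(config.corrupt.items()):
        for _ in range(count):
            donor_cfg = dataclasses.replace(base, seed=config.seed + 100_000 + k)
            donor, _gt = synthetic.generate_record(donor_cfg)
            bad = synthetic.corrupt_record(donor, mode, seed=config.seed + 200_000 + k)
            bad.subject_id = f"corrupt_{mode}_{k:03d}"
            out.append((bad, None))
            k += 1
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write every intermediate artifact under out_dir.

    Returns a bundle with the ledger, feature table and the three
    correlation reports. Reruns with an identical config are
    byte-identical.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = f"config_hash={config.config_hash} seed={config.seed}"
    config.to_yaml(out / "config.yaml")

    # stage 1: simulate
    try:
        cohort = simulate_cohort(config)
    except Exception as exc:
        raise RuntimeError(f"stage simulate failed: {exc}") from exc
    rec_dir = out / "records"
    rec_dir.mkdir(exist_ok=True)
    for rec, gt in cohort:
        write_record(rec, rec_dir / f"{rec.subject_id}.csv")
        if gt is not None:
            pd.DataFrame(dataclasses.asdict(gt)).to_csv(
                rec_dir / f"{rec.subject_id}.truth.csv", index=False
            )

    # stage 2: screen
    records = [rec for rec, _ in cohort]
    try:
        ledger, good = quality.screen_cohort(records)
    except Exception as exc:
        raise RuntimeError(f"stage screen failed: {exc}") from exc
    write_ledger(ledger, out / "screening_ledger.csv")
    log.info("screening: %d/%d records good", len(good), len(records))

    # stage 3: extract features
    try:
        table = features.build_feature_table(good, map_rule=config.map_rule)
    except Exception as exc:
        raise RuntimeError(f"stage extract failed: {exc}") from exc
    features.write_feature_table(table, out / "features.csv", header_comment=tag)

    # stage 4: correlate
    reports: dict[str, correlation.CorrelationReport] = {}
    if not table.empty:
        reports["subject_by_subject"] = correlation.analyze_subject_by_subject(
            table, bin_feature=config.bin_feature
        )
        correlation.render_reports(reports["subject_by_subject"], out, header=tag)
        coll_rows, exc_rows = [], []
        for bp in config.bp_targets:
            coll_rows.append(correlation.analyze_collective(table, bp_target=bp).rows)
            exc_rows.append(correlation.analyze_one_excellent_beat(table, bp_target=bp).rows)
        reports["collective"] = correlation.CorrelationReport(
            mode="collective", rows=pd.concat(coll_rows, ignore_index=True)
        )
        reports["one_excellent_beat"] = correlation.CorrelationReport(
            mode="one_excellent_beat", rows=pd.concat(exc_rows, ignore_index=True)
        )
        correlation.render_reports(reports["collective"], out, header=tag)
        correlation.render_reports(reports["one_excellent_beat"], out, header=tag)
    else:
        log.warning("no usable beats after screening; skipping correlation stage")

    return {"ledger": ledger, "features": table, "reports": reports, "config_hash": config.config_hash}


def load_records_dir(path) -> list[WaveformRecord]:
    """Read every native-format record in a directory (non-truth CSVs)."""
    path = Path(path)
    recs = []
    for p in sorted(path.glob("*.csv")):
        if p.name.endswith(".truth.csv"):
            continue
        recs.append(read_record(p))
    return recs
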