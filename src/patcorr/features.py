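"""Per-beat arterial-wave-propagation features and reference BP values.

Eight interval features per beat (seconds): five pulse arrival times from
the ECG R peak to PPG-family landmarks (PAT_RO, PAT_Ra, PAT_Rw1, PAT_Rb,
PAT_RS), one to the ABP systolic peak (PAT_RS*), the transit time from
ABP to PPG systolic peak (PTT_S*S), and the R-R interval. Reference SBP
and DBP are read from the *unfiltered* ABP at the detected S* and D*
samples so filter gain cannot bias the reference; MAP defaults to the
time-average of ABP over the beat (the monitor convention), with the
DBP + PP/3 estimate available as an alternative rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fiducials import BeatFiducials

log = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "pat_ro",
    "pat_ra",
    "pat_rw1",
    "pat_rb",
    "pat_rs",
    "pat_rsstar",
    "ptt_sstars",
    "rri",
]
BP_COLUMNS = ["sbp", "map", "dbp"]
TABLE_COLUMNS = ["subject_id", "beat_index", *FEATURE_COLUMNS, *BP_COLUMNS, "quality"]


class BeatRejected(ValueError):
    """A beat whose fiducials violate the interval contract."""


@dataclass
class BeatFeatures:
    subject_id: str
    beat_index: int
    pat_ro: float
    pat_ra: float
    pat_rw1: float
    pat_rb: float
    pat_rs: float
    pat_rsstar: float
    ptt_sstars: float
    rri: float
    sbp: float
    dbp: float
    map: float


def compute_beat_features(
    beat: BeatFiducials,
    next_r_time: float,
    abp: np.ndarray,
    fs: float,
    subject_id: str = "",
    map_rule: str = "waveform_mean",
) -> BeatFeatures:
    """Intervals and reference pressures for one complete beat.

    ``map_rule`` is ``"waveform_mean"`` (time-average of ABP over
    [R, next R)) or ``"dbp_pp3"`` (DBP + pulse pressure / 3).
    """
    if next_r_time <= beat.r_time:
        raise BeatRejected(f"beat {beat.beat_index}: next R not after R")
    if not beat.ordered(next_r_time):
        raise BeatRejected(f"beat {beat.beat_index}: fiducial ordering violated")
    r = beat.r_time
    feats = dict(
        pat_ro=beat.o_time - r,
        pat_ra=beat.a_time - r,
        pat_rw1=beat.w_time - r,
        pat_rb=beat.b_time - r,
        pat_rs=beat.s_time - r,
        pat_rsstar=beat.sstar_time - r,
        ptt_sstars=beat.s_time - beat.sstar_time,
        rri=next_r_time - r,
    )
    abp = np.asarray(abp, dtype=float)
    sbp = float(abp[int(round(beat.sstar_time * fs))])
    dbp = float(abp[int(round(beat.dstar_time * fs))])
    if map_rule == "waveform_mean":
        lo, hi = int(round(r * fs)), int(round(next_r_time * fs))
        map_ = float(np.mean(abp[lo:hi]))
    elif map_rule == "dbp_pp3":
        map_ = dbp + (sbp - dbp) / 3.0
    else:
        raise ValueError(f"unknown map_rule {map_rule!r}")
    return BeatFeatures(
        subject_id=subject_id, beat_index=beat.beat_index, sbp=sbp, dbp=dbp, map=map_, **feats
    )


def features_to_frame(rows: list[BeatFeatures], quality: dict[int, float] | None = None) -> pd.DataFrame:
    """One row per beat; ``quality`` maps beat_index -> beat SQI (optional)."""
    data = []
    for bf in rows:
        rec = {c: getattr(bf, c) for c in TABLE_COLUMNS if c != "quality"}
        rec["quality"] = (quality or {}).get(bf.beat_index, np.nan)
        data.append(rec)
    return pd.DataFrame(data, columns=TABLE_COLUMNS)


def extract_record_features(
    record,
    map_rule: str = "waveform_mean",
    with_quality: bool = True,
) -> pd.DataFrame:
    """Full single-record pipeline: filter, detect, pair, measure.

    Returns a feature table (possibly empty) with one row per surviving
    beat. Records where no beats can be paired yield an empty table.
    """
    from . import preprocess, quality as qmod
    from .fiducials import detect_abp_fiducials, detect_ppg_fiducials, detect_r_peaks, pair_beats

    ecg_f = preprocess.filter_ecg(record.ecg, record.fs)
    ppg_f = preprocess.filter_ppg(record.ppg, record.fs)
    derived = preprocess.derive_vpg_apg(ppg_f, record.fs)
    r_times = detect_r_peaks(ecg_f, record.fs)
    if len(r_times) < 2:
        log.info("record %s: fewer than 2 R peaks; no beats", record.subject_id)
        return pd.DataFrame(columns=TABLE_COLUMNS)
    abp_fid = detect_abp_fiducials(record.abp, record.fs, r_times)
    ppg_fid = detect_ppg_fiducials(derived, r_times)
    beats = pair_beats(r_times, abp_fid, ppg_fid)
    rows = []
    for beat in beats:
        try:
            rows.append(
                compute_beat_features(
                    beat,
                    next_r_time=float(r_times[beat.beat_index + 1]),
                    abp=record.abp,
                    fs=record.fs,
                    subject_id=record.subject_id,
                    map_rule=map_rule,
                )
            )
        except BeatRejected as exc:
            log.debug("record %s: %s", record.subject_id, exc)
    qscores = (
        qmod.beat_quality_scores(record, r_times, [b.beat_index for b in beats])
        if with_quality and rows
        else None
    )
    return features_to_frame(rows, qscores)


def build_feature_table(records, map_rule: str = "waveform_mean") -> pd.DataFrame:
    """Concatenate per-record feature tables for a screened cohort.

    The result has one row per surviving beat across all subjects; the
    per-subject beat counts (the "#PATs" bookkeeping) are
    ``table.groupby("subject_id").size()``.
    """
    frames = [extract_record_features(rec, map_rule=map_rule) for rec in records]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=TABLE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_feature_table(table: pd.DataFrame, path, header_comment: str | None = None) -> None:
    with open(path, "w", newline="") as f:
        if header_comment:
            f.write(f"#{header_comment}\n")
        table.to_csv(f, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
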