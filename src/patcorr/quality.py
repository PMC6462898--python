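"""Automated proxies for the visual record-screening rules.

Records are assigned exactly one of seven categories. Missing-signal
checks (absent channel, or flat line) take precedence over abnormality
checks, and channels are always examined in the fixed order ABP, ECG,
PPG, mirroring the category structure of the screening bookkeeping.

Abnormality is scored per channel with three reproducible metrics:

* beat detectability — fraction of inter-peak intervals from the
  channel's own peak detector that fall in a plausible heart-rate band;
* template SQI — mean correlation of each beat segment with the record's
  median beat template;
* (ABP only) physiologic plausibility — fraction of samples inside the
  20–300 mmHg band.

Thresholds are calibrated on the simulator's clean vs. corrupted
ensembles and are exposed as module constants; they are proxies for a
human annotator's judgement, not a reimplementation of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import WaveformRecord

FLATLINE_STD_RATIO = 1e-6  # std relative to max(range, 1) below which a channel is flat
SQI_THRESHOLD = 0.8
DETECTABILITY_THRESHOLD = 0.8
HR_BAND_BPM = (30.0, 200.0)
ABP_PLAUSIBLE_MMHG = (20.0, 300.0)
ABP_PLAUSIBLE_FRACTION = 0.9
MIN_BEATS = 3

_CHANNEL_ORDER = ("abp", "ecg", "ppg")


@dataclass
class QualityLabel:
    category: str
    metrics: dict[str, float] = field(default_factory=dict)


def _is_flat(x: np.ndarray) -> bool:
    return float(np.std(x)) < FLATLINE_STD_RATIO * max(float(np.ptp(x)), 1.0)


def _channel_peaks(x: np.ndarray, fs: float) -> np.ndarray:
    """Generic pulse/QRS peak detector used only for screening metrics."""
    distance = max(1, int(fs * 60.0 / HR_BAND_BPM[1]))
    peaks, _ = sps.find_peaks(x, distance=distance, prominence=0.3 * float(np.ptp(x)))
    return peaks


def _beat_detectability(x: np.ndarray, fs: float) -> float:
    peaks = _channel_peaks(x, fs)
    if len(peaks) < MIN_BEATS:
        return 0.0
    hr = 60.0 * fs / np.diff(peaks)
    ok = (hr >= HR_BAND_BPM[0]) & (hr <= HR_BAND_BPM[1])
    # also require a plausible number of beats for the record duration
    expected_min = len(x) / fs * HR_BAND_BPM[0] / 60.0
    if len(peaks) < 0.5 * expected_min:
        return 0.0
    return float(np.mean(ok))


def _template_sqi(x: np.ndarray, fs: float, anchors: np.ndarray | None = None) -> float:
    """Mean correlation of each beat segment with the median beat template."""
    peaks = anchors if anchors is not None else _channel_peaks(x, fs)
    if len(peaks) < MIN_BEATS:
        return 0.0
    med_int = int(np.median(np.diff(peaks)))
    if med_int < 4:
        return 0.0
    pre, post = int(0.25 * med_int), int(0.55 * med_int)
    segs = [
        x[p - pre : p + post]
        for p in peaks
        if p - pre >= 0 and p + post <= len(x)
    ]
    if len(segs) < MIN_BEATS:
        return 0.0
    mat = np.asarray(segs)
    template = np.median(mat, axis=0)
    t_sd = np.std(template)
    if t_sd == 0:
        return 0.0
    tc = template - template.mean()
    corrs = []
    for seg in mat:
        s_sd = np.std(seg)
        if s_sd == 0:
            corrs.append(0.0)
            continue
        corrs.append(float(np.mean((seg - seg.mean()) * tc) / (s_sd * t_sd)))
    return float(np.mean(corrs))


def screen_missing(record: WaveformRecord) -> QualityLabel | None:
    """Missing-signal label (absent channel or flat line), or None."""
    for chan in _CHANNEL_ORDER:
        x = getattr(record, chan)
        if x is None or _is_flat(x):
            return QualityLabel(category=f"missing_{chan}", metrics={f"{chan}_flat": 1.0})
    return None


def screen_abnormal(record: WaveformRecord) -> QualityLabel | None:
    """Abnormal-signal label for the first failing channel, or None."""
    metrics: dict[str, float] = {}
    for chan in _CHANNEL_ORDER:
        x = getattr(record, chan)
        det = _beat_detectability(x, record.fs)
        sqi = _template_sqi(x, record.fs)
        metrics[f"{chan}_detectability"] = det
        metrics[f"{chan}_sqi"] = sqi
        bad = det < DETECTABILITY_THRESHOLD or sqi < SQI_THRESHOLD
        if chan == "abp":
            lo, hi = ABP_PLAUSIBLE_MMHG
            plausible = float(np.mean((x >= lo) & (x <= hi)))
            metrics["abp_plausible_fraction"] = plausible
            bad = bad or plausible < ABP_PLAUSIBLE_FRACTION
        if bad:
            return QualityLabel(category=f"abnormal_{chan}", metrics=metrics)
    return None


def screen_record(record: WaveformRecord) -> QualityLabel:
    label = screen_missing(record)
    if label is not None:
        return label
    label = screen_abnormal(record)
    if label is not None:
        return label
    return QualityLabel(category="good")


def screen_cohort(records) -> tuple["ScreeningLedger", list[WaveformRecord]]:
    """Partition a cohort into the seven categories; forward good records."""
    from .records import ScreeningLedger

    ledger = ScreeningLedger()
    good: list[WaveformRecord] = []
    for rec in records:
        label = screen_record(rec)
        ledger.add(label.category, rec.subject_id)
        if label.category == "good":
            good.append(rec)
    return ledger, good


def beat_quality_scores(
    record: WaveformRecord, r_times: np.ndarray, beat_indices
) -> dict[int, float]:
    """Beat-level SQI: mean of the three channels' template correlations.

    Beat i spans [R_i, R_{i+1}); each channel's segment is correlated with
    that channel's median segment. Used to pick the "one excellent beat"
    per subject.
    """
    fs = record.fs
    r_idx = np.round(np.asarray(r_times) * fs).astype(int)
    if len(r_idx) < 2:
        return {i: 0.0 for i in beat_indices}
    seg_len = int(np.median(np.diff(r_idx)))
    channels = [np.asarray(getattr(record, c), dtype=float) for c in ("ecg", "ppg", "abp")]
    per_chan_corr: list[dict[int, float]] = []
    for x in channels:
        segs = {}
        for i in range(len(r_idx) - 1):
            lo = r_idx[i]
            if lo + seg_len <= len(x):
                segs[i] = x[lo : lo + seg_len]
        if len(segs) < MIN_BEATS:
            per_chan_corr.append({i: 0.0 for i in beat_indices})
            continue
        template = np.median(np.asarray(list(segs.values())), axis=0)
        tc = template - template.mean()
        t_sd = np.std(template)
        corrs = {}
        for i, seg in segs.items():
            s_sd = np.std(seg)
            corrs[i] = (
                float(np.mean((seg - seg.mean()) * tc) / (s_sd * t_sd))
                if s_sd > 0 and t_sd > 0
                else 0.0
            )
        per_chan_corr.append(corrs)
    return {
        i: float(np.mean([c.get(i, 0.0) for c in per_chan_corr])) for i in beat_indices
    }
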