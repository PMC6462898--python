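"""Per-beat fiducial detection on filtered ECG, PPG derivatives and ABP.

R peaks are found with a two-moving-average event detector on the squared
filtered ECG (the classic knowledge-based thresholding family). All other
fiducials are windowed extrema anchored on consecutive R peaks:

* ABP: S* is the global maximum in (R_i, R_{i+1}); D* the minimum after S*.
* PPG family, searched in (R_i, R_i + 0.9 RRI): S is the PPG maximum;
  w the VPG maximum before S; a the APG maximum before w; b the APG
  minimum between a and S; O the PPG minimum between R and a.

Ties break to the earliest sample, and beats violating the anatomical
ordering R < O <= a <= w <= b <= S are dropped rather than repaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import DerivedPPG

log = logging.getLogger(__name__)

# R detector constants (Elgendi-style two moving averages on squared ECG)
QRS_WINDOW_S = 0.097
BEAT_WINDOW_S = 0.611
BETA = 0.08
REFRACTORY_S = 0.25

#: PPG search window as a fraction of the local R-R interval; excludes the
#: next beat's upstroke.
PPG_WINDOW_FRACTION = 0.9


@dataclass
class BeatFiducials:
    """All eight fiducial times (s from record start) for one beat."""

    beat_index: int
    r_time: float
    o_time: float
    a_time: float
    w_time: float
    b_time: float
    s_time: float
    sstar_time: float
    dstar_time: float

    def ordered(self, next_r_time: float) -> bool:
        return (
            self.r_time
            < self.o_time
            <= self.a_time
            <= self.w_time
            <= self.b_time
            <= self.s_time
            < next_r_time
            and self.r_time < self.sstar_time <= self.s_time
            and self.dstar_time > self.sstar_time
        )


def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    w = max(1, w)
    c = np.convolve(x, np.ones(w) / w, mode="same")
    return c


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-peak times from a band-pass filtered ECG.

    Flat or too-short signals yield an empty array (logged), not an error.
    Every returned time is a local maximum of the input separated from its
    neighbours by at least the 250 ms refractory period.
    """
    ecg = np.asarray(ecg, dtype=float)
    if len(ecg) < int(BEAT_WINDOW_S * fs) + 2 or np.ptp(ecg) == 0:
        log.info("ECG flat or too short for R detection; returning no beats")
        return np.empty(0)
    y = ecg**2
    ma_qrs = _moving_average(y, int(round(QRS_WINDOW_S * fs)))
    ma_beat = _moving_average(y, int(round(BEAT_WINDOW_S * fs)))
    thr = ma_beat + BETA * float(np.mean(y))
    blocks = ma_qrs > thr

    peaks = []
    refractory = int(round(REFRACTORY_S * fs))
    min_block = max(1, int(round(QRS_WINDOW_S * fs / 2)))
    edges = np.flatnonzero(np.diff(blocks.astype(int)))
    starts = edges[blocks[edges + 1]] + 1 if len(edges) else np.empty(0, int)
    ends = edges[~blocks[edges + 1]] + 1 if len(edges) else np.empty(0, int)
    if blocks[0]:
        starts = np.concatenate(([0], starts))
    if blocks[-1]:
        ends = np.concatenate((ends, [len(blocks)]))
    for s, e in zip(starts, ends):
        if e - s < min_block:
            continue
        p = s + int(np.argmax(ecg[s:e]))
        if 0 < p < len(ecg) - 1 and ecg[p] >= ecg[p - 1] and ecg[p] >= ecg[p + 1]:
            if peaks and p - peaks[-1] < refractory:
                if ecg[p] > ecg[peaks[-1]]:
                    peaks[-1] = p
                continue
            peaks.append(p)
    if peaks:
        # amplitude-consistency pass: R spikes dominate T waves and noise
        # blips, so discard candidates far below the median accepted height
        heights = ecg[np.asarray(peaks)]
        keep = heights >= 0.5 * np.median(heights)
        peaks = [p for p, k in zip(peaks, keep) if k]
    return np.asarray(peaks, dtype=float) / fs


def _argext(x: np.ndarray, lo: int, hi: int, kind: str) -> int | None:
    """First extremum index in x[lo:hi]; None for an empty window."""
    if hi <= lo:
        return None
    seg = x[lo:hi]
    return lo + int(np.argmax(seg) if kind == "max" else np.argmin(seg))


def detect_abp_fiducials(
    abp: np.ndarray, fs: float, r_times: np.ndarray
) -> dict[int, tuple[float, float]]:
    """Per-beat (S*, D*) times keyed by beat index.

    Beats whose R-R window has no interior ABP peak (monotone segments,
    boundary maxima) are dropped and logged. The final partial beat, which
    has no following R, is never returned.
    """
    if len(r_times) == 0:
        raise ValueError("r_times must be non-empty")
    abp = np.asarray(abp, dtype=float)
    out: dict[int, tuple[float, float]] = {}
    r_idx = np.round(np.asarray(r_times) * fs).astype(int)
    for i in range(len(r_idx) - 1):
        lo, hi = r_idx[i] + 1, min(r_idx[i + 1], len(abp))
        p = _argext(abp, lo, hi, "max")
        if p is None or p in (lo, hi - 1):
            log.debug("beat %d: no interior ABP peak; dropped", i)
            continue
        if not (abp[p] >= abp[p - 1] and abp[p] >= abp[p + 1]):
            log.debug("beat %d: ABP maximum not a local peak; dropped", i)
            continue
        d = _argext(abp, p + 1, hi, "min")
        if d is None:
            continue
        out[i] = (p / fs, d / fs)
    return out


def detect_ppg_fiducials(
    derived: DerivedPPG, r_times: np.ndarray
) -> dict[int, tuple[float, float, float, float, float]]:
    """Per-beat (O, a, w, b, S) times keyed by beat index.

    The search window for beat i is (R_i, R_i + 0.9 RRI). Beats where any
    sub-window is degenerate or the ordering O <= a <= w <= b <= S fails
    are dropped and logged.
    """
    if len(r_times) == 0:
        raise ValueError("r_times must be non-empty")
    fs = derived.fs
    ppg, vpg, apg = derived.ppg, derived.vpg, derived.apg
    out: dict[int, tuple[float, float, float, float, float]] = {}
    r_idx = np.round(np.asarray(r_times) * fs).astype(int)
    for i in range(len(r_idx) - 1):
        rri = r_idx[i + 1] - r_idx[i]
        lo = r_idx[i] + 1
        hi = min(r_idx[i] + int(round(PPG_WINDOW_FRACTION * rri)), len(ppg))
        s = _argext(ppg, lo, hi, "max")
        if s is None or s in (lo, hi - 1):
            log.debug("beat %d: no interior PPG systolic peak; dropped", i)
            continue
        w = _argext(vpg, lo, s + 1, "max")
        if w is None:
            continue
        a = _argext(apg, lo, w + 1, "max")
        if a is None:
            continue
        b = _argext(apg, a + 1, s + 1, "min")
        if b is None:
            continue
        o = _argext(ppg, lo, a + 1, "min")
        if o is None:
            continue
        if not (o <= a <= w <= b <= s):
            log.debug("beat %d: PPG fiducial ordering violated; dropped", i)
            continue
        out[i] = tuple(idx / fs for idx in (o, a, w, b, s))  # type: ignore[assignment]
    return out


def pair_beats(
    r_times: np.ndarray,
    abp_fiducials: dict[int, tuple[float, float]],
    ppg_fiducials: dict[int, tuple[float, float, float, float, float]],
) -> list[BeatFiducials]:
    """Join per-channel fiducials on beat index; keep only complete beats.

    The returned list preserves ``beat_index`` for traceability; any beat
    violating the full ordering invariant (including S* placement) is
    discarded.
    """
    beats: list[BeatFiducials] = []
    for i in sorted(set(abp_fiducials) & set(ppg_fiducials)):
        sstar, dstar = abp_fiducials[i]
        o, a, w, b, s = ppg_fiducials[i]
        beat = BeatFiducials(
            beat_index=i,
            r_time=float(r_times[i]),
            o_time=o,
            a_time=a,
            w_time=w,
            b_time=b,
            s_time=s,
            sstar_time=sstar,
            dstar_time=dstar,
        )
        if not beat.ordered(next_r_time=float(r_times[i + 1])):
            log.debug("beat %d: cross-channel ordering violated; dropped", i)
            continue
        beats.append(beat)
    return beats
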