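"""Zero-phase band-pass filtering and PPG derivative computation.

ECG is band-passed 0.5–40 Hz with a Butterworth filter and PPG 0.5–10 Hz
with a Chebyshev type-II filter, each applied forward and backward
(``sosfiltfilt``) so interval measurements between channels are not biased
by filter phase delay. The first and second forward differences of the
filtered PPG give the velocity (VPG) and acceleration (APG)
photoplethysmograms used for fiducial detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

# Filter design constants. Orders are conventional for biosignal band-passes;
# the stopband attenuation of the PPG filter is modest on purpose — PPG
# harmonics above 10 Hz carry no fiducial information but aggressive filters
# ring on the sharp systolic upstroke.
ECG_BAND = (0.5, 40.0)  # Hz
PPG_BAND = (0.5, 10.0)  # Hz
ECG_ORDER = 4
PPG_ORDER = 4
PPG_STOPBAND_DB = 30.0


@dataclass
class DerivedPPG:
    """Filtered PPG with its first (VPG) and second (APG) derivatives."""

    ppg: np.ndarray  # filtered, original units
    vpg: np.ndarray  # units/s
    apg: np.ndarray  # units/s^2
    fs: float

    def __post_init__(self) -> None:
        if not (len(self.ppg) == len(self.vpg) == len(self.apg)):
            raise ValueError("ppg/vpg/apg length mismatch")


def _clip_band(band: tuple[float, float], fs: float) -> tuple[float, float]:
    lo, hi = band
    nyq = fs / 2.0
    if hi >= nyq:
        hi = 0.95 * nyq
        warnings.warn(
            f"upper band edge clipped to {hi:.3g} Hz (fs={fs} Hz gives Nyquist {nyq:.3g} Hz)",
            stacklevel=3,
        )
    return lo, hi


def _zero_phase(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(x) <= padlen:
        raise ValueError(
            f"signal of {len(x)} samples is shorter than the filter warm-up "
            f"length ({padlen + 1} samples)"
        )
    return sps.sosfiltfilt(sos, x)  # odd-reflection padding at both ends


def filter_ecg(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 0.5–40 Hz Butterworth band-pass. Length-preserving."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    band = _clip_band(ECG_BAND, fs)
    sos = sps.butter(ECG_ORDER, band, btype="bandpass", fs=fs, output="sos")
    return _zero_phase(sos, x)


def filter_ppg(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 0.5–10 Hz Chebyshev-II band-pass. Length-preserving."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    band = _clip_band(PPG_BAND, fs)
    sos = sps.cheby2(PPG_ORDER, PPG_STOPBAND_DB, band, btype="bandpass", fs=fs, output="sos")
    return _zero_phase(sos, x)


def derive_vpg_apg(ppg: np.ndarray, fs: float) -> DerivedPPG:
    """Forward-difference VPG and APG from a (filtered) PPG signal.

    Differences are scaled by ``fs`` so VPG/APG amplitudes are per-second
    and therefore sampling-rate invariant. The last sample of each
    difference is replicated so all three arrays share the input length.
    """
    ppg = np.asarray(ppg, dtype=float)
    if ppg.ndim != 1 or len(ppg) < 3:
        raise ValueError("need a 1-D PPG with at least 3 samples")
    vpg = np.diff(ppg) * fs
    vpg = np.append(vpg, vpg[-1])
    apg = np.diff(vpg) * fs
    apg = np.append(apg, apg[-1])
    return DerivedPPG(ppg=ppg, vpg=vpg, apg=apg, fs=fs)
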