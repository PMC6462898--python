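"""Synthetic synchronized ECG/PPG/ABP records with beat-level ground truth.

The generator emulates the statistical structure the correlation analyses
assume: quasi-periodic beats with heart-rate variability, a slowly varying
per-beat blood-pressure process, and PPG/ABP pulses whose arrival delay
after each ECG R peak is linearly coupled to systolic pressure::

    PAT_RS(i) = pat_rs_mean + coupling_slope * (SBP(i) - sbp_mean) + eps(i)

with ``eps ~ N(0, pat_noise_sd)``. The ABP systolic peak S* is placed at a
fixed fraction of PAT_RS after R, so the programmed decomposition
``PAT_RS = PAT_RS* + PTT_S*S`` holds exactly. Under this model the
population correlation between PAT_RS and SBP has the closed form::

    r = slope * sd_SBP / sqrt(slope^2 * sd_SBP^2 + pat_noise_sd^2)

which the analysis pipeline should recover from the rendered waveforms.

Pulse shapes are sums of Gaussian bumps plus a smooth exponential
diastolic runoff — invented morphology, chosen only so that every fiducial
the pipeline measures (O, a, w, b, S on PPG/VPG/APG; S*, D* on ABP) exists,
is unique, and is separable. Systolic peak times are programmed; the
remaining fiducial ground truths are located on the noise-free rendered
channels by the same windowed-extremum definitions the detectors use
(with plain forward differences, no filtering), so ground truth is
consistent with the waveforms to within one sample by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import QUALITY_CATEGORIES, WaveformRecord

# Physiologic clipping bounds for the AR(1) SBP walk (mmHg).
SBP_FLOOR = 60.0
SBP_CEILING = 250.0
DBP_FLOOR = 30.0
#: lag-1 autocorrelation of the per-beat SBP walk
BP_AR1_PHI = 0.9
#: SD of the beat-to-beat pulse-pressure jitter, mmHg
PP_JITTER_SD = 1.5

# ---------------------------------------------------------------------------
# pulse kernels (time in seconds, t = 0 at the systolic peak of each family)


def _gauss(t: np.ndarray, mu: float, sig: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sig) ** 2)


def _runoff(t: np.ndarray, t0: float, tau: float, width: float = 0.03) -> np.ndarray:
    """Smoothly switched-on exponential decay (diastolic runoff)."""
    return np.exp(-np.maximum(t - t0, 0.0) / tau) * 0.5 * (1.0 + np.tanh((t - t0) / width))


def _ecg_kernel(t: np.ndarray) -> np.ndarray:
    return (
        0.12 * _gauss(t, -0.19, 0.035)  # P wave
        - 0.08 * _gauss(t, -0.035, 0.012)  # Q dip
        + 1.00 * _gauss(t, 0.0, 0.012)  # R spike
        - 0.10 * _gauss(t, 0.045, 0.015)  # S dip
        + 0.22 * _gauss(t, 0.30, 0.055)  # T wave
    )


def _ppg_kernel(t: np.ndarray) -> np.ndarray:
    return (
        1.00 * _gauss(t, 0.0, 0.055)  # systolic wave
        + 0.38 * _gauss(t, 0.22, 0.09)  # diastolic wave
        + 0.32 * _runoff(t, 0.30, 0.30)  # perfusion runoff between beats
    )


def _abp_kernel(t: np.ndarray) -> np.ndarray:
    return (
        1.00 * _gauss(t, 0.0, 0.06)  # systolic wave
        + 0.30 * _gauss(t, 0.25, 0.09)  # dicrotic wave
        + 0.12 * _runoff(t, 0.32, 0.18)  # diastolic runoff
    )


#: kernel support relative to its systolic peak: contributions outside are dropped
_KERNEL_SPAN = (-0.45, 2.2)


def _kernel_peak_offset(kernel) -> float:
    """Continuous-time location of the kernel's global maximum (dense grid)."""
    t = np.arange(-0.3, 0.3, 1e-4)
    return float(t[np.argmax(kernel(t))])


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one simulated subject record.

    Defaults emulate the study conditions the analyses were run under:
    120 s records sampled at 125 Hz (150 beats at 75 bpm), ICU-like SBP
    variability of ~10 mmHg within a record, a mean R-to-PPG-peak arrival
    time of 0.35 s, and a negative PAT–SBP coupling.
    """

    n_beats: int = 150
    fs: float = 125.0
    hr_mean: float = 75.0  # beats/min
    hr_sd: float = 3.0  # beats/min
    sbp_mean: float = 120.0  # mmHg
    sbp_sd: float = 10.0  # mmHg
    dbp_offset: float = 40.0  # mean pulse pressure, mmHg
    coupling_slope: float = -0.002  # s/mmHg, change in PAT_RS per mmHg SBP
    pat_rs_mean: float = 0.35  # s
    pat_rsstar_fraction: float = 0.5  # S* position as a fraction of PAT_RS
    pat_noise_sd: float = 0.01  # s
    amplitude_noise_sd: float = 0.02  # relative to pulse amplitude
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.n_beats < 1:
            raise ValueError(f"n_beats must be >= 1, got {self.n_beats}")
        if not 0.0 < self.pat_rsstar_fraction < 1.0:
            raise ValueError("pat_rsstar_fraction must lie strictly in (0, 1)")
        if self.hr_mean <= 0:
            raise ValueError("hr_mean must be positive")
        for name in ("hr_sd", "sbp_sd", "pat_noise_sd", "amplitude_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.pat_rs_mean <= 0:
            raise ValueError("pat_rs_mean must be positive")
        if self.dbp_offset <= 0:
            raise ValueError("dbp_offset (mean pulse pressure) must be positive")


@dataclass
class GroundTruth:
    """Per-beat truth arrays, aligned by beat index.

    ``sbp``/``dbp`` are the programmed pressure process; ``map`` is the
    time-average of the noise-free rendered ABP over each R–R window (the
    same rule the feature extractor applies). ``pat_rs`` is the programmed
    R-to-S interval before sampling, so ``s_time - r_time == pat_rs`` and
    the additive split at S* is exact.
    """

    r_time: np.ndarray
    o_time: np.ndarray
    a_time: np.ndarray
    w_time: np.ndarray
    b_time: np.ndarray
    s_time: np.ndarray
    sstar_time: np.ndarray
    dstar_time: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    map: np.ndarray
    pat_rs: np.ndarray
    rri: np.ndarray

    @property
    def n_beats(self) -> int:
        return len(self.r_time)


def generate_bp_series(config: SyntheticConfig, rng: np.random.Generator | None = None):
    """Per-beat (sbp, dbp, map_proxy) from a bounded AR(1) walk.

    The walk is stationary around ``sbp_mean`` with marginal SD
    ``sbp_sd`` and lag-1 autocorrelation :data:`BP_AR1_PHI`, clipped to
    [60, 250] mmHg. DBP is SBP minus a jittered pulse pressure. The third
    array is the DBP + PP/3 proxy; the rendered-waveform MAP in
    :class:`GroundTruth` supersedes it once a record is rendered.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_beats
    phi = BP_AR1_PHI
    innov_sd = config.sbp_sd * np.sqrt(1.0 - phi**2)
    sbp = np.empty(n)
    x = rng.normal(0.0, config.sbp_sd)  # stationary start
    for i in range(n):
        sbp[i] = config.sbp_mean + x
        x = phi * x + rng.normal(0.0, innov_sd)
    np.clip(sbp, SBP_FLOOR, SBP_CEILING, out=sbp)
    pp = config.dbp_offset + rng.normal(0.0, PP_JITTER_SD, size=n)
    pp = np.clip(pp, 10.0, None)
    dbp = np.clip(sbp - pp, DBP_FLOOR, None)
    dbp = np.minimum(dbp, sbp - 10.0)
    map_proxy = dbp + (sbp - dbp) / 3.0
    return sbp, dbp, map_proxy


def _windowed_extremum(x: np.ndarray, lo: int, hi: int, kind: str) -> int:
    """Index of the first extremum of ``x[lo:hi]`` (ties -> earliest)."""
    seg = x[lo:hi]
    idx = int(np.argmax(seg) if kind == "max" else np.argmin(seg))
    return lo + idx


def generate_record(config: SyntheticConfig) -> tuple[WaveformRecord, GroundTruth]:
    """Render one subject's synchronized channels plus ground truth.

    Raises ``ValueError`` if the configured coupling/noise would yield a
    non-positive PAT or a PAT exceeding the beat period.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, fs = config.n_beats, config.fs

    # --- per-beat processes -------------------------------------------------
    sbp, dbp, _ = generate_bp_series(config, rng)
    hr = np.clip(rng.normal(config.hr_mean, config.hr_sd, size=n), 30.0, 200.0)
    rri = 60.0 / hr
    lead_in = 0.6
    r_time = lead_in + np.concatenate(([0.0], np.cumsum(rri[:-1])))
    pat_rs = (
        config.pat_rs_mean
        + config.coupling_slope * (sbp - config.sbp_mean)
        + rng.normal(0.0, config.pat_noise_sd, size=n)
    )
    if np.any(pat_rs <= 0):
        raise ValueError("configuration produced non-positive PAT values")
    if np.any(pat_rs >= rri):
        raise ValueError("configuration produced PAT values exceeding the beat period")
    s_time = r_time + pat_rs
    sstar_time = r_time + config.pat_rsstar_fraction * pat_rs

    # --- render -------------------------------------------------------------
    duration = r_time[-1] + rri[-1] + 0.8
    t = np.arange(int(round(duration * fs))) / fs
    ecg = np.zeros_like(t)
    ppg = np.zeros_like(t)
    abp = np.zeros_like(t)

    ecg_peak = _kernel_peak_offset(_ecg_kernel)
    ppg_peak = _kernel_peak_offset(_ppg_kernel)
    abp_peak = _kernel_peak_offset(_abp_kernel)
    ppg_norm = float(np.max(_ppg_kernel(np.arange(-0.3, 0.3, 1e-4))))
    abp_norm = float(np.max(_abp_kernel(np.arange(-0.3, 0.3, 1e-4))))

    gain = 1.0 + rng.normal(0.0, config.amplitude_noise_sd, size=n)

    def _add(channel, kernel, center, amp):
        lo = max(0, int(np.ceil((center + _KERNEL_SPAN[0]) * fs)))
        hi = min(len(t), int(np.floor((center + _KERNEL_SPAN[1]) * fs)) + 1)
        channel[lo:hi] += amp * kernel(t[lo:hi] - center)

    # virtual preceding beat: render only the runoff tails so the first real
    # beat has a monotone decreasing baseline into its pulse onset
    rr0 = float(np.mean(rri))
    _add(ppg, lambda u: 0.18 * _runoff(u, 0.30, 0.22) / ppg_norm, s_time[0] - rr0, 1.0)
    _add(
        abp,
        lambda u: 0.12 * _runoff(u, 0.32, 0.18) / abp_norm,
        sstar_time[0] - rr0,
        float(sbp[0] - dbp[0]),
    )

    # diastolic ABP baseline: DBP is an end-diastolic quantity, so dbp[i] is
    # anchored at the end of beat i (the next R time)
    next_r = np.append(r_time[1:], r_time[-1] + rri[-1])
    baseline = np.interp(t, next_r, dbp)
    abp += baseline

    for i in range(n):
        _add(ecg, _ecg_kernel, r_time[i] - ecg_peak, gain[i])
        _add(ppg, lambda u: _ppg_kernel(u) / ppg_norm, s_time[i] - ppg_peak, gain[i])
        # pulse amplitude chosen against the local baseline so the rendered
        # systolic peak value equals the programmed SBP
        base_at_peak = float(np.interp(sstar_time[i], next_r, dbp))
        _add(
            abp,
            lambda u: _abp_kernel(u) / abp_norm,
            sstar_time[i] - abp_peak,
            float(sbp[i]) - base_at_peak,
        )

    # --- locate the remaining fiducials on the clean render -----------------
    # O, a, w, b are extrema of the zero-phase band-passed PPG and its
    # forward-difference derivatives — that is their definition — so ground
    # truth applies the same definitional operators to the noise-free render.
    from .preprocess import derive_vpg_apg, filter_ppg

    derived_clean = derive_vpg_apg(filter_ppg(ppg, fs), fs)
    ppg_f, vpg, apg = derived_clean.ppg, derived_clean.vpg, derived_clean.apg
    o_t = np.empty(n)
    a_t = np.empty(n)
    w_t = np.empty(n)
    b_t = np.empty(n)
    d_t = np.empty(n)
    gt_map = np.empty(n)
    for i in range(n):
        ri = int(np.round(r_time[i] * fs))
        si = int(np.round(s_time[i] * fs))
        wi = _windowed_extremum(vpg, ri + 1, si + 1, "max")
        ai = _windowed_extremum(apg, ri + 1, wi + 1, "max")
        bi = _windowed_extremum(apg, ai + 1, si + 1, "min")
        oi = _windowed_extremum(ppg_f, ri + 1, ai + 1, "min")
        ssi = int(np.round(sstar_time[i] * fs))
        nri = int(np.round(next_r[i] * fs))
        di = _windowed_extremum(abp, ssi + 1, nri + 1, "min")
        o_t[i], a_t[i], w_t[i], b_t[i], d_t[i] = (
            oi / fs,
            ai / fs,
            wi / fs,
            bi / fs,
            di / fs,
        )
        gt_map[i] = float(np.mean(abp[ri:nri]))

    gt = GroundTruth(
        r_time=r_time,
        o_time=o_t,
        a_time=a_t,
        w_time=w_t,
        b_time=b_t,
        s_time=s_time,
        sstar_time=sstar_time,
        dstar_time=d_t,
        sbp=sbp,
        dbp=dbp,
        map=gt_map,
        pat_rs=pat_rs,
        rri=rri,
    )

    # --- measurement noise (after ground-truth extraction) -------------------
    if config.amplitude_noise_sd > 0:
        ecg = ecg + rng.normal(0.0, config.amplitude_noise_sd, size=len(t))
        ppg = ppg + rng.normal(0.0, config.amplitude_noise_sd, size=len(t))
        abp = abp + rng.normal(
            0.0, config.amplitude_noise_sd * config.dbp_offset, size=len(t)
        )

    record = WaveformRecord(
        subject_id=f"sim{config.seed:06d}", fs=fs, ecg=ecg, ppg=ppg, abp=abp
    )
    return record, gt


def corrupt_record(record: WaveformRecord, mode: str, seed: int = 0) -> WaveformRecord:
    """Return a copy of ``record`` with one channel destroyed.

    ``missing_*`` modes flat-line the named channel; ``abnormal_*`` modes
    bury its morphology under broadband noise several times the pulse
    amplitude (ABP additionally wanders outside the plausible pressure
    range). Corruption magnitudes are deliberately far beyond the
    screening thresholds. Other channels are untouched.
    """
    valid = set(QUALITY_CATEGORIES) - {"good"}
    if mode not in valid:
        raise ValueError(f"mode must be one of {sorted(valid)}, got {mode!r}")
    rng = np.random.default_rng(seed)
    kind, chan = mode.split("_")
    arrays = {c: getattr(record, c) for c in ("ecg", "ppg", "abp")}
    x = arrays[chan]
    if x is None:
        raise ValueError(f"record {record.subject_id!r} has no {chan} channel")
    n = len(x)
    if kind == "missing":
        arrays[chan] = np.full(n, float(np.mean(x)))
    else:
        amp = float(np.ptp(x))
        noise = rng.normal(0.0, 4.0 * amp, size=n)
        if chan == "abp":
            # push a large fraction of samples outside the 20-300 mmHg band
            noise += 200.0 * np.sin(2.0 * np.pi * 0.05 * np.arange(n) / record.fs)
        arrays[chan] = np.mean(x) + noise
    return WaveformRecord(subject_id=record.subject_id, fs=record.fs, **arrays)


@dataclass
class CohortConfig:
    """A cohort of subjects sharing a base configuration.

    Per-subject means are jittered (SBP mean SD 8 mmHg, HR mean SD 8 bpm)
    so between-subject offsets exist, as in real cohorts; within-subject
    dynamics follow the base config. Subject seeds are spawned
    deterministically from ``seed``.
    """

    n_subjects: int = 20
    base: SyntheticConfig = field(default_factory=SyntheticConfig)
    subject_sbp_sd: float = 8.0
    subject_hr_sd: float = 8.0
    seed: int = 0


def generate_cohort(cohort: CohortConfig) -> list[tuple[WaveformRecord, GroundTruth]]:
    """Generate ``n_subjects`` records with distinct IDs and ground truth."""
    rng = np.random.default_rng(cohort.seed)
    out = []
    for j in range(cohort.n_subjects):
        cfg = replace(
            cohort.base,
            sbp_mean=float(
                np.clip(
                    cohort.base.sbp_mean + rng.normal(0.0, cohort.subject_sbp_sd),
                    80.0,
                    200.0,
                )
            ),
            hr_mean=float(
                np.clip(cohort.base.hr_mean + rng.normal(0.0, cohort.subject_hr_sd), 45.0, 140.0)
            ),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        record, gt = generate_record(cfg)
        record.subject_id = f"subj{j:03d}"
        out.append((record, gt))
    return out
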