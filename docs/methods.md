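# Methods

This note documents the models, numerical choices and known limitations
behind `patcorr`, in the order the pipeline runs.

## Synthetic cohort model

The generator produces one subject's synchronized ECG, PPG and ABP
channels at a common sampling rate (default 125 Hz, 150 beats ≈ 120 s)
plus per-beat ground truth. It models the *statistical* structure the
correlation analyses rest on, not hemodynamics:

* **Beat times.** Per-beat heart rate is drawn i.i.d. from
  N(hr_mean, hr_sd), clipped to 30–200 bpm (defaults 75 ± 3 bpm); R-R
  intervals are its reciprocal. There is no respiratory sinus arrhythmia
  or trend structure.
* **Blood pressure.** Per-beat SBP follows a stationary AR(1) walk
  around `sbp_mean` with marginal SD `sbp_sd` and lag-1 autocorrelation
  0.9, clipped to 60–250 mmHg (defaults 120 ± 10 mmHg). DBP is SBP minus
  a pulse pressure jittered around `dbp_offset` (default 40 mmHg, SD
  1.5 mmHg), floored at 30 mmHg and kept ≥ 10 mmHg below SBP. The AR(1)
  choice gives within-record BP variation (without it, per-subject
  correlations would be undefined) while remaining a two-parameter
  process. The autocorrelation inflates the standard error of a record's
  mean SBP by √((1+φ)/(1−φ)) ≈ 4.36; the test suite uses that factor.
* **Coupling.** `PAT_RS(i) = pat_rs_mean + coupling_slope·(SBP(i) −
  sbp_mean) + ε(i)`, ε ~ N(0, pat_noise_sd) i.i.d. (defaults 0.35 s,
  −0.002 s/mmHg, 0.01 s). The ABP systolic peak S* sits at
  `pat_rsstar_fraction`·PAT_RS after R (default 0.5), so the
  decomposition PAT_RS = PAT_RS* + PTT_S*S is exact by construction.
  The implied population correlation is
  r = slope·σ_SBP / √(slope²σ_SBP² + σ_ε²); defaults give −0.89, and the
  parameter-recovery experiments use slope·σ_SBP = −0.02 s with
  σ_ε = 0.015 s for an analytic r of exactly −0.80. Configurations whose
  sampled PATs are non-positive or exceed the beat period are rejected.
* **Pulse shapes.** Invented morphology: each channel is a sum of
  per-beat kernels of Gaussian bumps plus a smoothly switched-on
  exponential diastolic runoff (plus P/Q/S/T bumps around the ECG R
  spike). Kernels were shaped only so that every fiducial the pipeline
  measures exists, is unique, and is separable: a dominant systolic
  peak, a distinct diastolic wave, and a monotone runoff into the next
  pulse onset so the pulse-foot minimum O is well defined. A virtual
  preceding beat contributes only its runoff tail so the first real beat
  has a proper onset valley. The ABP baseline interpolates per-beat DBP
  anchored at each beat's *end* (DBP is an end-diastolic quantity), and
  each pulse's amplitude is set against that baseline so the rendered
  systolic peak equals the programmed SBP (readout error ≲ 0.5 mmHg).
* **Noise.** `amplitude_noise_sd` (default 0.02, relative to pulse
  amplitude) acts twice: per-beat multiplicative gain jitter on the
  ECG/PPG kernels, and additive white noise on all channels (scaled by
  pulse pressure for ABP). Ground truth is extracted before noise is
  added.
* **Ground truth.** R, S and S* times are the programmed continuous
  values. O, a, w, b are *defined* as windowed extrema of the band-passed
  PPG and its forward differences, so ground truth applies exactly those
  definitional operators to the noise-free render; D* likewise on the
  raw ABP (the pipeline reads ABP unfiltered). Extrema of a 10 Hz
  band-limited second derivative are not stable to one sample between
  filtered and unfiltered versions of any reasonable pulse shape
  (measured shifts of 2–7 samples while shaping kernels), so defining
  truth through the measurement operators is what makes "consistent with
  the rendered waveforms to within one sample" achievable at all. The
  detection test remains informative: it verifies R-peak anchoring,
  window construction and pairing, and S/S* are checked against
  programmed times independent of any filter.
* **Cohorts.** `generate_cohort` jitters per-subject SBP and HR means
  (SD 8 mmHg / 8 bpm) so between-subject offsets exist; subject seeds
  are spawned deterministically from the cohort seed. Everything is
  bit-reproducible given the config.
* **Corruption.** `corrupt_record` flat-lines a channel (missing_*) or
  buries it under broadband noise at 4× the channel's range (abnormal_*;
  ABP additionally wanders ±200 mmHg so samples leave the plausible
  band). Magnitudes are deliberately far beyond the screening
  thresholds: the screening test is a separation check, not a
  threshold-sensitivity study.

What the generator does **not** emulate: real PPG/ABP morphology
(dicrotic notch variants, reflected waves), arrhythmia, motion artifact,
baseline wander, sensor drift, inter-channel desynchronization, and any
dependence of pulse shape on pressure beyond the programmed delay. Tests
passing on this cohort therefore validate the pipeline's mechanics and
statistics, not its readiness for clinical waveforms.

## Preprocessing

ECG: 4th-order Butterworth band-pass 0.5–40 Hz. PPG: 4th-order
Chebyshev II band-pass 0.5–10 Hz with 30 dB stopband attenuation. Both
are applied forward and backward (`sosfiltfilt`, odd-reflection padding)
for zero net phase — interval features compare times *across* channels,
so any phase delay would bias every PAT. The 30 dB attenuation is a
numerical choice: applied twice, 20 dB would leave a 1.0% DC residual,
exactly on the documented 1% bound, while 30 dB leaves 0.1% with
identical passband behavior at the 2–5 Hz pulse frequencies. Signals
shorter than the warm-up length are rejected; an upper band edge at or
above Nyquist is clipped with a warning. VPG and APG are forward
differences scaled by fs (units/s, units/s²), final samples replicated
to preserve length. ABP is never filtered: SBP/DBP are reference values
and filter gain would bias them.

## Fiducial detection

R peaks: two moving averages (97 ms and 611 ms) over the squared
filtered ECG; candidate blocks longer than half the QRS window yield
their ECG maximum; a 250 ms refractory period keeps the larger of two
close candidates; a final amplitude-consistency pass drops candidates
below half the median accepted height (T waves sit near 0.22 of the R
amplitude in the synthetic ECG and occasionally crossed the adaptive
threshold; the pass removes them without a second threshold parameter).
On default-noise synthetic records, sensitivity and positive
predictivity are both 1.0 over 20 records.

All other fiducials are windowed extrema anchored on consecutive R
peaks, ties to the earliest sample, times at sample resolution (no
sub-sample interpolation): S* is the ABP maximum in (R_i, R_{i+1})
(must be an interior local maximum, else the beat is dropped); D* the
ABP minimum after S*; within (R_i, R_i + 0.9·RRI), S is the PPG
maximum, w the VPG maximum before S, a the APG maximum before w, b the
APG minimum in (a, S), O the PPG minimum in (R, a). The 0.9·RRI window
excludes the next beat's upstroke. Beats violating
R < O ≤ a ≤ w ≤ b ≤ S < next R (or S* ∉ (R, S], D* ≤ S*) are dropped and
logged, never repaired. The final beat, lacking a following R, is always
excluded.

## Features

Each PAT is the fiducial time minus the beat's R time; PTT_S*S = S − S*;
RRI = next R − R. SBP and DBP are the raw ABP values at the detected S*
and D* samples. MAP defaults to the time-average of ABP over
[R, next R) — the monitor convention — because the source analyses
report MAP correlations without defining MAP; the DBP + PP/3 estimate is
available behind `map_rule="dbp_pp3"`. The additive identity
PAT_RS* + PTT_S*S = PAT_RS holds exactly for every row because both
terms are differences of the same three detected times.

Sample-resolution detection leaves a measurable quantization footprint:
under zero programmed coupling, the pipeline-estimated pooled r carries
a bias of −0.0027 ± 0.0009 (paired against ground-truth r over 20 ×
2000-beat records; the generator itself is unbiased, −0.0007 ± 0.0016
over 200 seeds). This is an order of magnitude below the standard error
of a single 2000-beat correlation estimate (≈ 0.022) and is documented
rather than corrected, since sub-sample interpolation is deliberately
out of scope.

## Quality screening

Automated proxies for what was originally a visual screen. Missing
checks precede abnormality checks; channels are always examined in the
order ABP, ECG, PPG, so exactly one of seven categories results.
A channel is *missing* if absent or flat (SD < 1e−6 of its range).
A channel is *abnormal* if its beat detectability (fraction of
inter-peak intervals from a generic prominence-based peak detector
falling in 30–200 bpm, with a floor on the plausible beat count) falls
below 0.8, or its template SQI (mean correlation of beat segments with
the record's median beat) falls below 0.8; ABP additionally requires
≥ 90% of samples within 20–300 mmHg. Thresholds are module constants
calibrated once on the simulator's clean vs. corrupted ensembles, which
separate by a wide margin — they are a reproducible stand-in for a human
annotator, not a re-derivation of those judgements, and records abnormal
in only a segment are screened as whole records.

The beat-level SQI (mean of the three channels' template correlations
for the beat's R-R segment) drives the "one excellent beat" selection,
replacing manual annotation; ties resolve to the earliest beat.

## Correlation analyses

`pearson` is the standard sample coefficient with zero-variance inputs
raising an explicit error rather than returning 0. Strength bins are
half-open on |r| ([0, 0.2) very weak … [0.8, 1.0] very strong) so every
value is binned exactly once; 0.795 is "strong". Subject mode computes
r per subject (≥ 2 beats required), an unweighted mean ± SD across
subjects, and bin counts on one configured feature (default PAT_RS*).
Collective mode pools all beats with no per-subject centering — pooling
is not averaging, and a constructed two-subject example in the test
suite shows the pooled sign inverting against both within-subject signs.
One-excellent-beat mode correlates across subjects using each subject's
best-SQI beat. No p-values or multiple-testing corrections are computed:
the analyses report r only, and no regression or BP-prediction model is
in scope.

Reports are delimited tables with r rounded to two decimals, a
"Mean ± STD" footer in subject mode, and every file stamped with the
run-config hash.

## Problem sizes in tests and the acceptance script

Simulation-backed checks use sizes chosen to make their statistics
decisive while the whole suite stays fast: 100-beat noise-free records
for localization; 100 × 8-beat records for the additivity identity;
20 × 2000 beats for coupling recovery (SE of each pooled r ≈ 0.022,
so the ±0.05 band on the 20-seed mean is ~10 SE of that mean wide); 50
clean + 50 corrupted 30-beat records for screening. The demo cohort in
`analysis/` uses 121 subjects × 111 beats to mirror the scale of the
original screened dataset (121 subjects, ~13 300 pooled beats).

## Known limitations

* Morphology is synthetic; absolute PAT values and fiducial spacings
  are plausible but not calibrated to any population.
* The screening thresholds are tuned to the simulator's corruption
  modes; real artifact (intermittent noise, partial flat-lines) would
  need re-calibration against annotated data.
* The WFDB adapter maps channel aliases (II/ECG, PLETH, ABP/ART) and
  requires the optional `wfdb` package; multi-segment layouts and
  per-channel sampling rates are not supported (mismatched rates are an
  error by design — the pipeline never resamples).
* Within-subject SBP ranges in real ICU records are unknown to the
  generator; its defaults are free parameters of the simulation, not
  claims about any archive.
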