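import numpy as np
import pytest

from patcorr.synthetic import SyntheticConfig, generate_record


@pytest.fixture(scope="session")
def noisefree_record():
    """100-beat record with no measurement or PAT noise (fs = 125 Hz)."""
    cfg = SyntheticConfig(n_beats=100, amplitude_noise_sd=0.0, pat_noise_sd=0.0, seed=3)
    return generate_record(cfg)


@pytest.fixture(scope="session")
def clean_record():
    """40-beat record at default (mild) noise levels."""
    cfg = SyntheticConfig(n_beats=40, seed=1)
    return generate_record(cfg)


@pytest.fixture(scope="session")
def detected_beats(noisefree_record):
    """Paired fiducials for the noise-free record, via the full chain."""
    from patcorr import preprocess
    from patcorr.fiducials import (
        detect_abp_fiducials,
        detect_ppg_fiducials,
        detect_r_peaks,
        pair_beats,
    )

    rec, gt = noisefree_record
    ecg_f = preprocess.filter_ecg(rec.ecg, rec.fs)
    derived = preprocess.derive_vpg_apg(preprocess.filter_ppg(rec.ppg, rec.fs), rec.fs)
    r_times = detect_r_peaks(ecg_f, rec.fs)
    beats = pair_beats(
        r_times,
        detect_abp_fiducials(rec.abp, rec.fs, r_times),
        detect_ppg_fiducials(derived, r_times),
    )
    return r_times, beats


def brute_force_pearson(x, y):
    """Independent oracle: covariance over SD product, by explicit sums."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    cov = sum((xi - mx) * (yi - my) for xi, yi in zip(x, y))
    vx = sum((xi - mx) ** 2 for xi in x)
    vy = sum((yi - my) ** 2 for yi in y)
    return cov / np.sqrt(vx * vy)
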