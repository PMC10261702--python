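import numpy as np
import pytest

from pasa import AcquisitionConfig, simulate_dataset
from pasa.pipeline import band_feature_table, extract_features


def brute_force_welch(x, fs, window_seconds=5e-6, overlap=0.60):
    """Independent Welch oracle: explicit segment loop, Hamming window,
    per-segment mean removal, mean of one-sided periodograms."""
    from scipy.signal import get_window

    nperseg = int(np.floor(window_seconds * fs + 0.5))
    step = int(np.floor((1.0 - overlap) * nperseg))
    win = get_window("hamming", nperseg)
    scale = 1.0 / (fs * np.sum(win ** 2))
    psds = []
    start = 0
    while start + nperseg <= len(x):
        seg = x[start:start + nperseg]
        seg = seg - seg.mean()
        spec = np.fft.rfft(seg * win)
        p = np.abs(spec) ** 2 * scale
        p[1:] *= 2.0
        if nperseg % 2 == 0:
            p[-1] /= 2.0
        psds.append(p)
        start += step
    return np.fft.rfftfreq(nperseg, 1.0 / fs), np.mean(psds, axis=0)


@pytest.fixture
def fast_config():
    """Reduced-rate acquisition (0.25 GS/s, 25 us records) for cheap tests;
    the Welch window still holds 1250 samples and the 1-20 MHz band is
    fully below Nyquist."""
    return AcquisitionConfig(sampling_rate=2.5e8, record_length=6250)


@pytest.fixture(scope="session")
def cohort():
    """Default study-size synthetic cohort (12 normal / 15 SCC / 12 BCC) at
    full acquisition settings, reduced to its analysis products."""
    sample_set = simulate_dataset({"normal": 12, "SCC": 15, "BCC": 12}, seed=1)
    fm, curves = extract_features(sample_set)
    labels = dict(zip(sample_set.sample_ids, sample_set.labels))
    band_df = band_feature_table(curves, labels)
    return {"features": fm, "bands": band_df}
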