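"""Calibration and power-spectral analysis of photoacoustic waveforms.

A tissue waveform is first calibrated by dividing it by the peak-to-peak
amplitude of the blackbody reference recorded at the same optical
wavelength, which cancels the per-wavelength laser-energy variation.  The
power spectral density of the calibrated signal is then estimated with
Welch's method (5 us moving Hamming window, 60% overlap), and the spectra
of all scan wavelengths are stacked into a physiochemical spectrogram
(PAPCS): a wavelength x ultrasonic-frequency power matrix for one sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as _sig

__all__ = [
    "PASignalRecord",
    "PowerSpectrum",
    "PAPCS",
    "peak_to_peak",
    "calibrate",
    "welch_psd",
    "build_papcs",
]


@dataclass
class PASignalRecord:
    """One time-domain PA waveform for a (sample, wavelength, position) triple."""

    waveform: np.ndarray
    sampling_rate: float
    wavelength: float
    sample_id: str = ""
    position: int = 0
    calibrated: bool = False
    #: set by the simulator when a record contains no absorber signal
    pure_noise: bool = False

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.waveform.ndim != 1:
            raise ValueError("waveform must be one-dimensional")
        if not np.all(np.isfinite(self.waveform)):
            raise ValueError("waveform contains non-finite samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return self.waveform.size / self.sampling_rate


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectral density estimate (units^2/Hz)."""

    frequencies: np.ndarray
    psd: np.ndarray
    window_length: float
    overlap_fraction: float

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.psd, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise ValueError("frequencies and psd must be equal-length 1-D arrays")
        if np.any(f < 0) or not np.all(np.diff(f) > 0):
            raise ValueError("frequencies must be non-negative and increasing")
        if np.any(p < -0.0) or not np.all(np.isfinite(p)):
            raise ValueError("psd must be finite and non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "psd", p)


@dataclass(frozen=True)
class PAPCS:
    """Physiochemical spectrogram: PSD over (optical wavelength x frequency)."""

    sample_id: str
    wavelengths: np.ndarray
    frequencies: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, float)
        f = np.asarray(self.frequencies, float)
        p = np.asarray(self.power, float)
        if p.shape != (wl.size, f.size):
            raise ValueError("power must be |wavelengths| x |frequencies|")
        if np.any(p < 0):
            raise ValueError("PAPCS entries must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.power, index=self.wavelengths, columns=self.frequencies)

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "wavelength_nm"
        df.to_csv(path)

    def plot(self, ax=None):
        """Heatmap of the spectrogram (wavelength on x, frequency on y)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mesh = ax.pcolormesh(self.wavelengths, self.frequencies / 1e6, self.power.T,
                             shading="nearest")
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("frequency (MHz)")
        ax.figure.colorbar(mesh, ax=ax, label="PSD")
        return ax


def peak_to_peak(record: PASignalRecord) -> float:
    """max - min of the waveform; zero only for a constant record."""
    w = record.waveform
    if w.size == 0:
        raise ValueError("cannot take peak-to-peak of an empty waveform")
    return float(np.max(w) - np.min(w))


#: blackbody peak-to-peak below this is treated as a dead reference channel
DEAD_REFERENCE_TOL = 1e-12


def calibrate(tissue_record: PASignalRecord, blackbody_record: PASignalRecord,
              tol: float = DEAD_REFERENCE_TOL) -> PASignalRecord:
    """Divide a tissue waveform by the blackbody peak-to-peak at its wavelength."""
    if tissue_record.calibrated:
        raise ValueError("record is already calibrated")
    if not math.isclose(tissue_record.wavelength, blackbody_record.wavelength):
        raise ValueError(
            f"wavelength mismatch: tissue {tissue_record.wavelength} nm vs "
            f"blackbody {blackbody_record.wavelength} nm"
        )
    p2p = peak_to_peak(blackbody_record)
    if p2p <= tol:
        raise ValueError(
            f"blackbody reference at {blackbody_record.wavelength} nm has "
            f"peak-to-peak {p2p:.3g} <= {tol:.3g}: dead reference channel"
        )
    return replace(tissue_record, waveform=tissue_record.waveform / p2p, calibrated=True)


def _window_samples(window_seconds: float, sampling_rate: float) -> int:
    # round half up so e.g. 5 us at 2.5 GS/s -> exactly 12500 samples
    return int(math.floor(window_seconds * sampling_rate + 0.5))


def welch_psd(record: PASignalRecord, window_seconds: float = 5e-6,
              overlap: float = 0.60, time_gate: tuple[float, float] | None = None
              ) -> PowerSpectrum:
    """Welch PSD with a Hamming window.

    Parameters
    ----------
    record
        Input waveform; must span at least one window.
    window_seconds
        Moving-window length in seconds (default 5 us -> 200 kHz resolution).
    overlap
        Fractional overlap of consecutive segments (default 0.60).
    time_gate
        Optional (t_start, t_end) region of interest in seconds; default is
        the full record.

    The FFT length equals the window length (no zero padding) and each
    segment has its mean removed before windowing.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    x = record.waveform
    fs = record.sampling_rate
    if time_gate is not None:
        i0, i1 = (int(round(t * fs)) for t in time_gate)
        if not 0 <= i0 < i1 <= x.size:
            raise ValueError("time_gate outside the record")
        x = x[i0:i1]
    nperseg = _window_samples(window_seconds, fs)
    if x.size < nperseg:
        raise ValueError(
            f"waveform has {x.size} samples but one {window_seconds * 1e6:g} us "
            f"window needs {nperseg} at {fs:g} S/s"
        )
    step = int(math.floor((1.0 - overlap) * nperseg))
    freqs, psd = _sig.welch(
        x, fs=fs, window="hamming", nperseg=nperseg, noverlap=nperseg - step,
        nfft=nperseg, detrend="constant", scaling="density", average="mean",
    )
    # round-off in the periodogram can produce tiny negative zeros
    psd = np.maximum(psd, 0.0)
    return PowerSpectrum(frequencies=freqs, psd=psd,
                         window_length=window_seconds, overlap_fraction=overlap)


def build_papcs(records: Iterable[PASignalRecord], sample_id: str | None = None,
                wavelengths: Sequence[float] | None = None,
                window_seconds: float = 5e-6, overlap: float = 0.60) -> PAPCS:
    """Stack position-averaged Welch spectra of one sample into a PAPCS.

    Each record must be calibrated; per wavelength, the PSD is computed for
    every measurement position and averaged, and rows are ordered by
    increasing wavelength.  If ``wavelengths`` is given, all of them must be
    present.
    """
    records = list(records)
    if not records:
        raise ValueError("no records supplied")
    fs = {r.sampling_rate for r in records}
    if len(fs) != 1:
        raise ValueError("records mix sampling rates")
    if any(not r.calibrated for r in records):
        raise ValueError("all records must be calibrated before building a PAPCS")
    ids = {r.sample_id for r in records}
    if sample_id is None:
        if len(ids) != 1:
            raise ValueError("records mix sample ids; pass sample_id explicitly")
        sample_id = next(iter(ids))

    by_wl: dict[float, list[PASignalRecord]] = {}
    for r in records:
        by_wl.setdefault(float(r.wavelength), []).append(r)
    if wavelengths is not None:
        missing = sorted(set(float(w) for w in wavelengths) - set(by_wl))
        if missing:
            raise ValueError(f"missing wavelengths: {missing}")
        by_wl = {w: by_wl[float(w)] for w in wavelengths}

    wl_sorted = sorted(by_wl)
    rows, freqs = [], None
    for wl in wl_sorted:
        spectra = [welch_psd(r, window_seconds, overlap) for r in by_wl[wl]]
        freqs = spectra[0].frequencies
        rows.append(np.mean([s.psd for s in spectra], axis=0))
    return PAPCS(sample_id=sample_id, wavelengths=np.array(wl_sorted),
                 frequencies=freqs, power=np.vstack(rows))
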