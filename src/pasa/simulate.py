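"""Forward simulator for multiwavelength photoacoustic tissue measurements.

Emulates the acquisition geometry of an ex vivo skin-tissue scan: an OPO
laser stepping through 51 wavelengths (1200-1700 nm, 10 nm steps) plus a
690 nm reference shot, a needle hydrophone with a 1-20 MHz bandwidth
sampled at 2.5 GS/s, 64-shot averaging, two measurement positions per
sample, and a blackbody reference channel that sees 10% of every pulse.

Each tissue phantom is a sparse collection of spherical absorbers whose
composition (lipid / collagen / water volume fractions) depends on the
tissue class: normal skin carries more lipid and collagen than squamous
cell carcinoma (SCC), which carries more than basal cell carcinoma (BCC).
A sphere of radius ``a`` emits a bipolar pressure pulse of duration
``2a/c``; radii are drawn so the characteristic frequency content falls
inside the 1-8 MHz analysis band.  Waveform amplitude is linear in each
chromophore fraction and in the pulse energy, and 64-shot averaging is
modelled as dividing the additive-noise standard deviation by sqrt(64).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import signal as _sig

from .chromophores import (
    REFERENCE_WAVELENGTH,
    WAVELENGTH_GRID,
    ChromophoreSpectrum,
    builtin_spectra,
)
from .core import PASignalRecord

__all__ = [
    "CLASS_LABELS",
    "CLASS_FRACTIONS",
    "EnergyProfile",
    "AcquisitionConfig",
    "TissuePhantom",
    "SampleSet",
    "generate_phantom",
    "simulate_pa_signal",
    "simulate_blackbody_reference",
    "simulate_dataset",
]

CLASS_LABELS = ("normal", "SCC", "BCC")

#: (mean, std) of the chromophore volume fractions per tissue class.  The
#: normal > SCC > BCC ordering of lipid and collagen drives every downstream
#: group difference; water is class-independent.  Draws are truncated at 0
#: and rescaled if the three fractions exceed unity.
CLASS_FRACTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "normal": {"lipid": (0.30, 0.05), "collagen": (0.35, 0.05), "water": (0.25, 0.05)},
    "SCC": {"lipid": (0.20, 0.05), "collagen": (0.25, 0.05), "water": (0.25, 0.05)},
    "BCC": {"lipid": (0.12, 0.05), "collagen": (0.17, 0.05), "water": (0.25, 0.05)},
}

#: default absorber radius range (mm): characteristic frequency c/(2a)
#: between 1.5 and 6 MHz at c = 1500 m/s, comfortably inside 1-8 MHz.
DEFAULT_RADIUS_RANGE_MM = (0.125, 0.5)

_ARRIVAL_WINDOW_S = (2e-6, 20e-6)


@dataclass(frozen=True)
class EnergyProfile:
    """Per-wavelength laser pulse energy (mJ) with multiplicative fluctuation.

    The deterministic base profile is a smooth OPO-like tuning curve bounded
    to [0.1, 0.5] mJ; shot-to-shot fluctuation is a multiplicative Gaussian
    factor with relative standard deviation ``fluctuation_std``.
    """

    low: float = 0.1
    high: float = 0.5
    fluctuation_std: float = 0.05

    def base(self, wavelength: float) -> float:
        mid = 0.5 * (self.low + self.high)
        amp = 0.4 * (self.high - self.low)
        val = mid + amp * np.cos((wavelength - 1450.0) / 500.0 * np.pi)
        return float(np.clip(val, self.low, self.high))

    def sample(self, wavelength: float, rng: np.random.Generator) -> float:
        return self.base(wavelength) * (1.0 + self.fluctuation_std * rng.standard_normal())


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and electronics of the simulated scan."""

    wavelengths: tuple[float, ...] = tuple(WAVELENGTH_GRID)
    sampling_rate: float = 2.5e9
    record_length: int = 62500  # 25 us: >= 9 Welch windows at 60% overlap
    pulse_energy: EnergyProfile = field(default_factory=EnergyProfile)
    transducer_band: tuple[float, float] = (1e6, 20e6)
    noise_sigma: float = 0.01
    n_averages: int = 64
    n_positions: int = 2
    sound_speed: float = 1500.0
    pulse_shape: str = "sine"  # "sine" (smooth bipolar) or "nwave" (sawtooth)
    blackbody_radius_mm: float = 0.375

    def __post_init__(self) -> None:
        if len(set(self.wavelengths)) != len(self.wavelengths):
            raise ValueError("wavelengths must be unique")
        if self.sampling_rate <= 2 * self.transducer_band[1]:
            raise ValueError("sampling_rate must exceed twice the upper band edge")
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")
        if self.pulse_shape not in ("sine", "nwave"):
            raise ValueError("pulse_shape must be 'sine' or 'nwave'")

    @property
    def noise_std_effective(self) -> float:
        """Post-averaging noise standard deviation (sigma / sqrt(n_averages))."""
        return self.noise_sigma / np.sqrt(self.n_averages)


@dataclass(frozen=True)
class TissuePhantom:
    """Composition and absorber geometry of one simulated tissue sample."""

    class_label: str
    lipid_fraction: float
    collagen_fraction: float
    water_fraction: float
    absorber_radii: tuple[float, ...]  # mm
    absorber_positions: tuple[float, ...]  # axial distance from detector, mm
    seed: int = 0

    def __post_init__(self) -> None:
        fr = (self.lipid_fraction, self.collagen_fraction, self.water_fraction)
        if any(f < 0 for f in fr) or sum(fr) > 1 + 1e-12:
            raise ValueError("fractions must be non-negative and sum to <= 1")
        if any(r <= 0 for r in self.absorber_radii):
            raise ValueError("absorber radii must be positive")
        if len(self.absorber_radii) != len(self.absorber_positions):
            raise ValueError("radii and positions must align")

    @property
    def fractions(self) -> dict[str, float]:
        return {"lipid": self.lipid_fraction, "collagen": self.collagen_fraction,
                "water": self.water_fraction}


@dataclass
class SampleSet:
    """A full simulated cohort: phantoms, tissue records and blackbody records."""

    phantoms: list[TissuePhantom]
    sample_ids: list[str]
    labels: list[str]
    #: (sample_id, wavelength, position) -> record
    signals: dict[tuple[str, float, int], PASignalRecord]
    #: wavelength -> reference record (one per acquisition session)
    blackbody: dict[float, PASignalRecord]
    config: AcquisitionConfig

    def records_for(self, sample_id: str) -> list[PASignalRecord]:
        return [r for (sid, _, _), r in self.signals.items() if sid == sample_id]

    def validate(self) -> None:
        for sid in self.sample_ids:
            for wl in self.config.wavelengths:
                for pos in range(self.config.n_positions):
                    if (sid, float(wl), pos) not in self.signals:
                        raise ValueError(f"missing record {(sid, wl, pos)}")
        for wl in self.config.wavelengths:
            if float(wl) not in self.blackbody:
                raise ValueError(f"missing blackbody record at {wl} nm")


def generate_phantom(class_label: str, seed: int,
                     n_absorbers: int = 25,
                     radius_range_mm: tuple[float, float] = DEFAULT_RADIUS_RANGE_MM,
                     sound_speed: float = 1500.0) -> TissuePhantom:
    """Draw one tissue phantom from the class-specific composition model.

    Radii are log-uniform over ``radius_range_mm``; axial positions are
    uniform over the distances that arrive 2-20 us after the laser shot.
    """
    if class_label not in CLASS_FRACTIONS:
        raise ValueError(
            f"unknown class label {class_label!r}; valid labels: {CLASS_LABELS}")
    rng = np.random.default_rng(seed)
    draws = {}
    for chrom, (mean, std) in CLASS_FRACTIONS[class_label].items():
        draws[chrom] = max(0.0, mean + std * rng.standard_normal())
    total = sum(draws.values())
    if total > 1.0:
        draws = {k: v / total for k, v in draws.items()}
    lo, hi = radius_range_mm
    radii = np.exp(rng.uniform(np.log(lo), np.log(hi), n_absorbers))
    dist_mm = rng.uniform(_ARRIVAL_WINDOW_S[0] * sound_speed * 1e3,
                          _ARRIVAL_WINDOW_S[1] * sound_speed * 1e3, n_absorbers)
    return TissuePhantom(
        class_label=class_label,
        lipid_fraction=draws["lipid"],
        collagen_fraction=draws["collagen"],
        water_fraction=draws["water"],
        absorber_radii=tuple(radii),
        absorber_positions=tuple(dist_mm),
        seed=int(seed),
    )


@lru_cache(maxsize=8)
def _bandpass_sos(band: tuple[float, float], fs: float):
    return _sig.butter(4, band, btype="band", fs=fs, output="sos")


def _add_pulse(out: np.ndarray, fs: float, t0: float, half_dur: float,
               amp: float, shape: str) -> None:
    """Accumulate one bipolar pulse centred at t0 with half-duration a/c."""
    i0 = max(0, int(np.ceil((t0 - half_dur) * fs)))
    i1 = min(out.size, int(np.floor((t0 + half_dur) * fs)) + 1)
    if i1 <= i0:
        return
    t = np.arange(i0, i1) / fs - t0
    if shape == "sine":
        # one full sine cycle over [-a/c, a/c]: smooth, spectral peak ~ c/(2a)
        out[i0:i1] += amp * np.sin(np.pi * (t + half_dur) / half_dur)
    else:  # sawtooth N-wave
        out[i0:i1] += amp * t / half_dur


def _synthesize(pulses: Sequence[tuple[float, float, float]],
                config: AcquisitionConfig, noise_rng: np.random.Generator | None
                ) -> np.ndarray:
    """Sum pulses (t0, half_dur, amp), band-limit, add post-averaging noise."""
    out = np.zeros(config.record_length)
    for t0, half_dur, amp in pulses:
        _add_pulse(out, config.sampling_rate, t0, half_dur, amp, config.pulse_shape)
    if np.any(out):
        sos = _bandpass_sos(config.transducer_band, config.sampling_rate)
        out = _sig.sosfiltfilt(sos, out)
    if noise_rng is not None and config.noise_sigma > 0:
        out = out + config.noise_std_effective * noise_rng.standard_normal(out.size)
    return out


def _mu_a_total(phantom: TissuePhantom, wavelength: float,
                spectra: Mapping[str, ChromophoreSpectrum]) -> float:
    return sum(frac * spectra[name].at(wavelength)
               for name, frac in phantom.fractions.items())


def _check_on_grid(wavelength: float, config: AcquisitionConfig) -> float:
    for wl in config.wavelengths:
        if np.isclose(wl, wavelength):
            return float(wl)
    raise ValueError(f"wavelength {wavelength} nm is not on the acquisition grid")


def _position_distances(phantom: TissuePhantom, position: int) -> np.ndarray:
    """Absorber distances as seen from one measurement direction.

    Position 0 is the phantom's stored geometry; other positions view the
    same absorbers with a +/-5% path-length jitter, deterministic in
    (phantom.seed, position) and independent of wavelength.
    """
    d = np.asarray(phantom.absorber_positions, float)
    if position == 0:
        return d
    rng = np.random.default_rng([phantom.seed & 0x7FFFFFFF, 7919, position])
    return d * (1.0 + 0.05 * rng.standard_normal(d.size))


def simulate_pa_signal(phantom: TissuePhantom, wavelength: float,
                       config: AcquisitionConfig, position: int = 0,
                       seed: int = 0, energy: float | None = None,
                       spectra: Mapping[str, ChromophoreSpectrum] | None = None,
                       sample_id: str = "") -> PASignalRecord:
    """Simulate one averaged tissue waveform at one wavelength and position.

    Each absorber of radius ``a`` (mm) contributes a bipolar pulse of
    duration ``2a/c`` with amplitude proportional to
    ``mu_a_total(wavelength) * pulse_energy * a``.  If ``energy`` is None,
    the per-shot energy (base profile x fluctuation) is drawn from ``seed``.
    """
    wavelength = _check_on_grid(wavelength, config)
    if spectra is None:
        spectra = builtin_spectra()
    if energy is None:
        energy = config.pulse_energy.sample(
            wavelength, np.random.default_rng([seed & 0x7FFFFFFF, 17]))
    mu = _mu_a_total(phantom, wavelength, spectra)
    c = config.sound_speed
    pure_noise = len(phantom.absorber_radii) == 0
    if pure_noise:
        warnings.warn("phantom has no absorbers; returning a pure-noise record")
    pulses = []
    dists = _position_distances(phantom, position)
    for a_mm, d_mm in zip(phantom.absorber_radii, dists):
        half_dur = a_mm * 1e-3 / c
        amp = mu * energy * (a_mm / 0.375)
        pulses.append((d_mm * 1e-3 / c, half_dur, amp))
    noise_rng = np.random.default_rng(seed)
    waveform = _synthesize(pulses, config, noise_rng)
    return PASignalRecord(waveform=waveform, sampling_rate=config.sampling_rate,
                          wavelength=wavelength, sample_id=sample_id,
                          position=position, pure_noise=pure_noise)


def simulate_blackbody_reference(wavelength: float, config: AcquisitionConfig,
                                 seed: int = 0, energy: float | None = None
                                 ) -> PASignalRecord:
    """Simulate the blackbody reference shot at one wavelength.

    A single bipolar pulse whose peak-to-peak amplitude is proportional to
    the pulse energy (including its fluctuation draw when ``energy`` is
    None); same noise contract as the tissue channel.
    """
    wavelength = _check_on_grid(wavelength, config)
    if energy is None:
        energy = config.pulse_energy.sample(
            wavelength, np.random.default_rng([seed & 0x7FFFFFFF, 17]))
    a_mm = config.blackbody_radius_mm
    half_dur = a_mm * 1e-3 / config.sound_speed
    t0 = 0.5 * config.record_length / config.sampling_rate
    noise_rng = np.random.default_rng(seed)
    waveform = _synthesize([(t0, half_dur, float(energy))], config, noise_rng)
    return PASignalRecord(waveform=waveform, sampling_rate=config.sampling_rate,
                          wavelength=wavelength, sample_id="blackbody")


def simulate_dataset(n_per_class: Mapping[str, int] | Sequence[int],
                     config: AcquisitionConfig | None = None,
                     seed: int = 0) -> SampleSet:
    """Simulate a complete cohort of tissue samples.

    ``n_per_class`` maps class label to count (or gives counts in the order
    normal, SCC, BCC; the study cohort is 12/15/12).  One laser-energy
    fluctuation is drawn per wavelength and shared between the tissue and
    blackbody channels of that wavelength, mirroring the 10% pick-off of
    every physical pulse.
    """
    if config is None:
        config = AcquisitionConfig()
    if not isinstance(n_per_class, Mapping):
        n_per_class = dict(zip(CLASS_LABELS, n_per_class))
    for label, n in n_per_class.items():
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {label!r}")
        if n < 1:
            raise ValueError("need at least one sample per requested class")

    master = np.random.default_rng(seed)
    spectra = builtin_spectra()
    energies = {float(wl): config.pulse_energy.sample(wl, master)
                for wl in config.wavelengths}

    blackbody = {}
    for wl in config.wavelengths:
        bb_seed = int(master.integers(2**31))
        blackbody[float(wl)] = simulate_blackbody_reference(
            wl, config, seed=bb_seed, energy=energies[float(wl)])

    phantoms, sample_ids, labels = [], [], []
    signals: dict[tuple[str, float, int], PASignalRecord] = {}
    idx = 0
    for label in CLASS_LABELS:
        for _ in range(n_per_class.get(label, 0)):
            idx += 1
            sid = f"S{idx:03d}"
            phantom = generate_phantom(label, seed=int(master.integers(2**31)),
                                       sound_speed=config.sound_speed)
            phantoms.append(phantom)
            sample_ids.append(sid)
            labels.append(label)
            for wl in config.wavelengths:
                for pos in range(config.n_positions):
                    rec_seed = int(master.integers(2**31))
                    rec = simulate_pa_signal(
                        phantom, wl, config, position=pos, seed=rec_seed,
                        energy=energies[float(wl)], spectra=spectra, sample_id=sid)
                    signals[(sid, float(wl), pos)] = rec
    return SampleSet(phantoms=phantoms, sample_ids=sample_ids, labels=labels,
                     signals=signals, blackbody=blackbody, config=config)
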