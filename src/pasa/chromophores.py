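"""Built-in relative optical-absorption spectra of skin chromophores.

The analysis band runs from 1200 to 1700 nm in 10 nm steps, where lipid
absorbs strongly near 1210 nm and in the 1600-1700 nm overtone region and
collagen near 1320 nm, plus a short-wavelength reference point at 690 nm
where none of the three chromophores absorbs strongly.  The spectra here are
smooth analytic stand-ins (Gaussian peaks on a small baseline, a monotone
rising water term) shaped to reproduce those qualitative features; they are
in arbitrary relative units.  Literature spectra on the same grid may be
substituted via :func:`ChromophoreSpectrum.from_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChromophoreSpectrum",
    "REFERENCE_WAVELENGTH",
    "SCAN_WAVELENGTHS",
    "WAVELENGTH_GRID",
    "builtin_spectrum",
    "builtin_spectra",
]

#: Reference wavelength (nm) used to normalise the APSD (outside the scan range).
REFERENCE_WAVELENGTH = 690.0

#: Scan grid: 1200-1700 nm in 10 nm steps (51 wavelengths).
SCAN_WAVELENGTHS = np.arange(1200.0, 1701.0, 10.0)

#: Full simulation grid: reference wavelength plus the scan grid.
WAVELENGTH_GRID = np.concatenate(([REFERENCE_WAVELENGTH], SCAN_WAVELENGTHS))

_VALID_NAMES = ("lipid", "collagen", "water")


@dataclass(frozen=True)
class ChromophoreSpectrum:
    """Relative absorption coefficient of one chromophore on a wavelength grid."""

    name: str
    wavelengths: np.ndarray
    mu_a: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        mu = np.asarray(self.mu_a, dtype=float)
        if wl.ndim != 1 or wl.shape != mu.shape:
            raise ValueError("wavelengths and mu_a must be 1-D arrays of equal length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(mu)) or np.any(mu < 0):
            raise ValueError("mu_a must be finite and non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "mu_a", mu)

    def at(self, wavelength: float) -> float:
        """Absorption at a grid wavelength (exact match required)."""
        idx = np.flatnonzero(np.isclose(self.wavelengths, wavelength))
        if idx.size == 0:
            raise ValueError(
                f"wavelength {wavelength} nm is not on the spectrum grid "
                f"({self.wavelengths[0]:.0f}-{self.wavelengths[-1]:.0f} nm)"
            )
        return float(self.mu_a[idx[0]])

    @classmethod
    def from_table(cls, name: str, wavelengths, mu_a) -> "ChromophoreSpectrum":
        return cls(name=name, wavelengths=np.asarray(wavelengths, float),
                   mu_a=np.asarray(mu_a, float))


def _gaussian(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def builtin_spectrum(name: str, wavelengths=None) -> ChromophoreSpectrum:
    """Built-in spectrum for ``lipid``, ``collagen`` or ``water``.

    Lipid: peaks at 1210 nm and a 1720 nm overtone whose shoulder dominates
    1600-1700 nm.  Collagen: peak at 1320 nm with a weaker 1700 nm rise.
    Water: small, monotonically rising with wavelength.  All three are small
    and featureless at the 690 nm reference point.
    """
    if name not in _VALID_NAMES:
        raise ValueError(f"unknown chromophore {name!r}; valid names: {_VALID_NAMES}")
    wl = WAVELENGTH_GRID if wavelengths is None else np.asarray(wavelengths, float)
    if name == "lipid":
        mu = 0.02 + 1.0 * _gaussian(wl, 1210.0, 15.0) + 1.3 * _gaussian(wl, 1720.0, 45.0)
    elif name == "collagen":
        mu = 0.02 + 1.0 * _gaussian(wl, 1320.0, 18.0) + 0.45 * _gaussian(wl, 1720.0, 55.0)
    else:  # water
        mu = 0.08 + 0.30 * (wl - wl.min()) / (wl.max() - wl.min())
    return ChromophoreSpectrum(name=name, wavelengths=wl, mu_a=mu)


def builtin_spectra(wavelengths=None) -> dict[str, ChromophoreSpectrum]:
    """All three built-in chromophore spectra keyed by name."""
    return {n: builtin_spectrum(n, wavelengths) for n in _VALID_NAMES}
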