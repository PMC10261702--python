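"""Relative APSD features from calibrated PA power spectra.

The area of power spectral density (APSD) of a waveform is the integral of
its PSD over the 1-8 MHz analysis band.  Normalising the APSD at scan
wavelength lambda by the APSD at a reference wavelength lambda0 (690 nm)
gives the dimensionless relative APSD,

    relative APSD(lambda) = (int_{f0}^{f1} p(f) df)_lambda
                            / (int_{f0}^{f1} p(f) df)_lambda0,

which tracks the relative optical absorption, hence the relative
chromophore content, at that wavelength.  Curves are computed per
measurement position and averaged, then summarised over three absorption
bands (lipid 1200-1240 nm, collagen 1300-1340 nm, lipid overtone
1600-1700 nm) whose 21 wavelengths form the classification feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import PASignalRecord, PowerSpectrum, welch_psd

__all__ = [
    "BANDS",
    "FEATURE_WAVELENGTHS",
    "DEFAULT_F0",
    "DEFAULT_F1",
    "APSDValue",
    "RelativeAPSDCurve",
    "BandFeature",
    "FeatureMatrix",
    "apsd",
    "relative_apsd",
    "position_average",
    "band_average",
    "build_feature_matrix",
    "curve_from_records",
]

DEFAULT_F0 = 1e6
DEFAULT_F1 = 8e6

#: fixed chromophore absorption bands (nm)
BANDS: dict[str, tuple[float, ...]] = {
    "lipid_low": tuple(np.arange(1200.0, 1241.0, 10.0)),
    "collagen": tuple(np.arange(1300.0, 1341.0, 10.0)),
    "lipid_high": tuple(np.arange(1600.0, 1701.0, 10.0)),
}

#: the 21 feature wavelengths in fixed column order
FEATURE_WAVELENGTHS: tuple[float, ...] = (
    BANDS["lipid_low"] + BANDS["collagen"] + BANDS["lipid_high"]
)


@dataclass(frozen=True)
class APSDValue:
    sample_id: str
    wavelength: float
    position: int
    apsd: float
    f0: float = DEFAULT_F0
    f1: float = DEFAULT_F1

    def __post_init__(self) -> None:
        if self.apsd < 0:
            raise ValueError("APSD must be non-negative")


@dataclass(frozen=True)
class RelativeAPSDCurve:
    """Per-wavelength relative APSD of one sample (position-averaged or not)."""

    sample_id: str
    wavelengths: np.ndarray
    values: np.ndarray
    reference_wavelength: float = 690.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, float)
        v = np.asarray(self.values, float)
        if wl.shape != v.shape or wl.ndim != 1:
            raise ValueError("wavelengths and values must be equal-length 1-D arrays")
        if np.any(v < 0):
            raise ValueError("relative APSD values must be non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    def at(self, wavelength: float) -> float:
        idx = np.flatnonzero(np.isclose(self.wavelengths, wavelength))
        if idx.size == 0:
            raise ValueError(f"wavelength {wavelength} nm not in curve")
        return float(self.values[idx[0]])


@dataclass(frozen=True)
class BandFeature:
    sample_id: str
    band: str
    value: float

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}; valid: {tuple(BANDS)}")


@dataclass(frozen=True)
class FeatureMatrix:
    """n_samples x 21 relative-APSD matrix with class labels."""

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    features: np.ndarray
    feature_names: tuple[str, ...] = tuple(f"{w:.0f}nm" for w in FEATURE_WAVELENGTHS)

    def __post_init__(self) -> None:
        X = np.asarray(self.features, float)
        if X.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("features must be n_samples x n_feature_names")
        if not np.all(np.isfinite(X)):
            raise ValueError("feature matrix contains missing entries")
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels must align with sample_ids")
        object.__setattr__(self, "features", X)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, wavelength: float) -> np.ndarray:
        name = f"{wavelength:.0f}nm"
        if name not in self.feature_names:
            raise ValueError(f"{name} is not a feature column")
        return self.features[:, self.feature_names.index(name)]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, index=list(self.sample_ids),
                          columns=list(self.feature_names))
        df.insert(0, "label", list(self.labels))
        df.index.name = "sample_id"
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="sample_id")
        labels = tuple(df.pop("label"))
        return cls(sample_ids=tuple(df.index.astype(str)), labels=labels,
                   features=df.to_numpy(float), feature_names=tuple(df.columns))


def apsd(power_spectrum: PowerSpectrum, f0: float = DEFAULT_F0,
         f1: float = DEFAULT_F1, sample_id: str = "", wavelength: float = 0.0,
         position: int = 0) -> APSDValue:
    """Integrate the PSD over [f0, f1] (trapezoid, interpolated band edges)."""
    f = power_spectrum.frequencies
    p = power_spectrum.psd
    if not f0 < f1:
        raise ValueError("need f0 < f1")
    if f0 < f[0] or f1 > f[-1]:
        raise ValueError(
            f"cutoffs [{f0:g}, {f1:g}] Hz outside the spectrum grid "
            f"[{f[0]:g}, {f[-1]:g}] Hz")
    inner = (f > f0) & (f < f1)
    xs = np.concatenate(([f0], f[inner], [f1]))
    ys = np.concatenate(([np.interp(f0, f, p)], p[inner], [np.interp(f1, f, p)]))
    value = float(np.trapezoid(ys, xs))
    return APSDValue(sample_id=sample_id, wavelength=wavelength,
                     position=position, apsd=max(value, 0.0), f0=f0, f1=f1)


def relative_apsd(apsd_at_lambda: APSDValue | float,
                  apsd_at_lambda0: APSDValue | float) -> float:
    """Ratio of the APSD at lambda to the APSD at the reference wavelength."""
    num = apsd_at_lambda.apsd if isinstance(apsd_at_lambda, APSDValue) else float(apsd_at_lambda)
    den = apsd_at_lambda0.apsd if isinstance(apsd_at_lambda0, APSDValue) else float(apsd_at_lambda0)
    if den <= 0:
        raise ValueError("reference APSD is not positive: unusable reference measurement")
    return num / den


def position_average(curves: Sequence[RelativeAPSDCurve]) -> RelativeAPSDCurve:
    """Arithmetic mean of per-position curves on a common wavelength grid."""
    if not curves:
        raise ValueError("need at least one curve")
    wl0 = curves[0].wavelengths
    for c in curves[1:]:
        if c.wavelengths.shape != wl0.shape or not np.allclose(c.wavelengths, wl0):
            raise ValueError("curves have mismatched wavelength grids")
    values = np.mean([c.values for c in curves], axis=0)
    return RelativeAPSDCurve(sample_id=curves[0].sample_id, wavelengths=wl0,
                             values=values,
                             reference_wavelength=curves[0].reference_wavelength)


def band_average(curve: RelativeAPSDCurve, band: str) -> BandFeature:
    """Mean relative APSD over one band's fixed wavelength set."""
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}; valid: {tuple(BANDS)}")
    missing = [w for w in BANDS[band]
               if not np.any(np.isclose(curve.wavelengths, w))]
    if missing:
        raise ValueError(f"curve is missing band wavelengths: {missing}")
    vals = [curve.at(w) for w in BANDS[band]]
    return BandFeature(sample_id=curve.sample_id, band=band,
                       value=float(np.mean(vals)))


def curve_from_records(records: Iterable[PASignalRecord],
                       reference_wavelength: float = 690.0,
                       f0: float = DEFAULT_F0, f1: float = DEFAULT_F1,
                       window_seconds: float = 5e-6, overlap: float = 0.60
                       ) -> RelativeAPSDCurve:
    """Position-averaged relative APSD curve of one sample.

    For each position, the relative APSD is formed against that position's
    own reference-wavelength record; the per-position curves are then
    averaged (relative-APSD-level averaging).
    """
    by_pos: dict[int, dict[float, PASignalRecord]] = {}
    sid = ""
    for r in records:
        by_pos.setdefault(r.position, {})[float(r.wavelength)] = r
        sid = r.sample_id or sid
    curves = []
    for pos in sorted(by_pos):
        recs = by_pos[pos]
        if reference_wavelength not in recs:
            raise ValueError(
                f"position {pos} lacks the {reference_wavelength:g} nm reference record")
        ref = apsd(welch_psd(recs[reference_wavelength], window_seconds, overlap),
                   f0, f1)
        wls = sorted(w for w in recs if w != reference_wavelength)
        vals = [relative_apsd(
                    apsd(welch_psd(recs[w], window_seconds, overlap), f0, f1), ref)
                for w in wls]
        curves.append(RelativeAPSDCurve(sample_id=sid, wavelengths=np.array(wls),
                                        values=np.array(vals),
                                        reference_wavelength=reference_wavelength))
    return position_average(curves)


def build_feature_matrix(sample_curves: Mapping[str, RelativeAPSDCurve],
                         labels: Mapping[str, str]) -> FeatureMatrix:
    """Assemble the n x 21 classification matrix from per-sample curves."""
    rows, sids, labs = [], [], []
    for sid, curve in sample_curves.items():
        missing = [w for w in FEATURE_WAVELENGTHS
                   if not np.any(np.isclose(curve.wavelengths, w))]
        if missing:
            raise ValueError(
                f"sample {sid!r} is missing feature wavelengths: {missing}")
        rows.append([curve.at(w) for w in FEATURE_WAVELENGTHS])
        sids.append(sid)
        labs.append(labels[sid])
    return FeatureMatrix(sample_ids=tuple(sids), labels=tuple(labs),
                         features=np.array(rows))
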