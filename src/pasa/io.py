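"""Persistence of simulated sample sets.

Waveforms go into one HDF5 container (tissue signals, blackbody references,
and their index arrays), accompanied by a plain-text JSON manifest and an
optional CSV metadata export (labels, fractions, seeds) for quick
inspection without touching the container.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import PASignalRecord
from .simulate import AcquisitionConfig, EnergyProfile, SampleSet, TissuePhantom

__all__ = ["save_sample_set", "load_sample_set", "metadata_frame"]


def metadata_frame(sample_set: SampleSet) -> pd.DataFrame:
    rows = []
    for sid, label, ph in zip(sample_set.sample_ids, sample_set.labels,
                              sample_set.phantoms):
        rows.append({"sample_id": sid, "label": label,
                     "lipid_fraction": ph.lipid_fraction,
                     "collagen_fraction": ph.collagen_fraction,
                     "water_fraction": ph.water_fraction,
                     "n_absorbers": len(ph.absorber_radii), "seed": ph.seed})
    return pd.DataFrame(rows).set_index("sample_id")


def _config_dict(cfg: AcquisitionConfig) -> dict:
    return {
        "wavelengths": list(map(float, cfg.wavelengths)),
        "sampling_rate": cfg.sampling_rate,
        "record_length": cfg.record_length,
        "pulse_energy": {"low": cfg.pulse_energy.low, "high": cfg.pulse_energy.high,
                         "fluctuation_std": cfg.pulse_energy.fluctuation_std},
        "transducer_band": list(cfg.transducer_band),
        "noise_sigma": cfg.noise_sigma,
        "n_averages": cfg.n_averages,
        "n_positions": cfg.n_positions,
        "sound_speed": cfg.sound_speed,
        "pulse_shape": cfg.pulse_shape,
        "blackbody_radius_mm": cfg.blackbody_radius_mm,
    }


def config_from_dict(d: dict) -> AcquisitionConfig:
    d = dict(d)
    energy = d.pop("pulse_energy", {})
    return AcquisitionConfig(
        wavelengths=tuple(d.pop("wavelengths")),
        transducer_band=tuple(d.pop("transducer_band")),
        pulse_energy=EnergyProfile(**energy),
        **d,
    )


def save_sample_set(sample_set: SampleSet, path, metadata_csv=None) -> None:
    """Write the sample set to ``path`` (HDF5) plus ``path``.manifest.json."""
    path = Path(path)
    keys = sorted(sample_set.signals)
    n = len(keys)
    length = sample_set.config.record_length
    with h5py.File(path, "w") as f:
        sig = f.create_dataset("signals/waveforms", shape=(n, length), dtype="f8")
        for i, k in enumerate(keys):
            sig[i] = sample_set.signals[k].waveform
        f.create_dataset("signals/sample_id",
                         data=np.array([k[0] for k in keys], dtype="S16"))
        f.create_dataset("signals/wavelength", data=[k[1] for k in keys])
        f.create_dataset("signals/position", data=[k[2] for k in keys])
        bb_wl = sorted(sample_set.blackbody)
        f.create_dataset("blackbody/wavelength", data=bb_wl)
        f.create_dataset("blackbody/waveforms",
                         data=np.vstack([sample_set.blackbody[w].waveform
                                         for w in bb_wl]))
        meta = f.create_group("samples")
        meta.create_dataset("sample_id",
                            data=np.array(sample_set.sample_ids, dtype="S16"))
        meta.create_dataset("label", data=np.array(sample_set.labels, dtype="S16"))
        for fieldname in ("lipid_fraction", "collagen_fraction", "water_fraction",
                          "seed"):
            meta.create_dataset(fieldname, data=[getattr(p, fieldname)
                                                 for p in sample_set.phantoms])
        meta.create_dataset("absorber_radii", data=np.vstack(
            [p.absorber_radii for p in sample_set.phantoms]))
        meta.create_dataset("absorber_positions", data=np.vstack(
            [p.absorber_positions for p in sample_set.phantoms]))
        f.attrs["config_json"] = json.dumps(_config_dict(sample_set.config))

    manifest = {
        "n_samples": len(sample_set.sample_ids),
        "n_tissue_records": n,
        "n_blackbody_records": len(sample_set.blackbody),
        "labels": {lab: sample_set.labels.count(lab)
                   for lab in dict.fromkeys(sample_set.labels)},
        "config": _config_dict(sample_set.config),
    }
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=2))
    if metadata_csv is not None:
        metadata_frame(sample_set).to_csv(metadata_csv)


def load_sample_set(path) -> SampleSet:
    path = Path(path)
    with h5py.File(path, "r") as f:
        config = config_from_dict(json.loads(f.attrs["config_json"]))
        sids = [s.decode() for s in f["signals/sample_id"][:]]
        wls = f["signals/wavelength"][:]
        poss = f["signals/position"][:]
        waves = f["signals/waveforms"][:]
        signals = {}
        for sid, wl, pos, w in zip(sids, wls, poss, waves):
            signals[(sid, float(wl), int(pos))] = PASignalRecord(
                waveform=w, sampling_rate=config.sampling_rate,
                wavelength=float(wl), sample_id=sid, position=int(pos))
        blackbody = {}
        for wl, w in zip(f["blackbody/wavelength"][:], f["blackbody/waveforms"][:]):
            blackbody[float(wl)] = PASignalRecord(
                waveform=w, sampling_rate=config.sampling_rate,
                wavelength=float(wl), sample_id="blackbody")
        meta = f["samples"]
        sample_ids = [s.decode() for s in meta["sample_id"][:]]
        labels = [s.decode() for s in meta["label"][:]]
        phantoms = []
        for i in range(len(sample_ids)):
            phantoms.append(TissuePhantom(
                class_label=labels[i],
                lipid_fraction=float(meta["lipid_fraction"][i]),
                collagen_fraction=float(meta["collagen_fraction"][i]),
                water_fraction=float(meta["water_fraction"][i]),
                absorber_radii=tuple(meta["absorber_radii"][i]),
                absorber_positions=tuple(meta["absorber_positions"][i]),
                seed=int(meta["seed"][i])))
    return SampleSet(phantoms=phantoms, sample_ids=sample_ids, labels=labels,
                     signals=signals, blackbody=blackbody, config=config)
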