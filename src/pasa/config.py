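"""Pipeline configuration: one YAML-serialisable object covering every stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import DEFAULT_F0, DEFAULT_F1
from .classify import SVMConfig
from .io import _config_dict, config_from_dict
from .simulate import AcquisitionConfig

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    svm: SVMConfig = field(default_factory=SVMConfig)
    n_per_class: dict = field(default_factory=lambda: {"normal": 12, "SCC": 15,
                                                       "BCC": 12})
    f0: float = DEFAULT_F0
    f1: float = DEFAULT_F1
    reference_wavelength: float = 690.0
    welch_window_seconds: float = 5e-6
    welch_overlap: float = 0.60
    output_dir: str = "pasa_run"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.f0 < self.f1:
            raise ValueError("need f0 < f1")
        if self.reference_wavelength not in [float(w) for w in
                                             self.acquisition.wavelengths]:
            raise ValueError("reference wavelength must be on the acquisition grid")
        if not 0 <= self.welch_overlap < 1:
            raise ValueError("welch_overlap must be in [0, 1)")
        for label, n in self.n_per_class.items():
            if n < 1:
                raise ValueError(f"n_per_class[{label!r}] must be >= 1")

    def to_dict(self) -> dict:
        return {
            "acquisition": _config_dict(self.acquisition),
            "svm": {"C_grid": list(map(float, self.svm.C_grid)),
                    "gamma_grid": list(map(float, self.svm.gamma_grid)),
                    "seed": self.svm.seed, "standardize": self.svm.standardize,
                    "n_folds": self.svm.n_folds, "inner_folds": self.svm.inner_folds},
            "n_per_class": dict(self.n_per_class),
            "f0": self.f0, "f1": self.f1,
            "reference_wavelength": self.reference_wavelength,
            "welch_window_seconds": self.welch_window_seconds,
            "welch_overlap": self.welch_overlap,
            "output_dir": self.output_dir, "seed": self.seed,
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        acq = config_from_dict(d.pop("acquisition")) if "acquisition" in d \
            else AcquisitionConfig()
        svm_d = d.pop("svm", {})
        if "C_grid" in svm_d:
            svm_d["C_grid"] = tuple(svm_d["C_grid"])
        if "gamma_grid" in svm_d:
            svm_d["gamma_grid"] = tuple(svm_d["gamma_grid"])
        cfg = cls(acquisition=acq, svm=SVMConfig(**svm_d), **d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
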