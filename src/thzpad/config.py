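"""YAML run configuration: geometry, thresholds, dataset composition."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .detection import Thresholds
from .materials import material_library
from .optics import Geometry
from .synthetic import DatasetConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs besides its input files."""

    geometry: Geometry = field(default_factory=Geometry)
    thresholds: Thresholds = field(default_factory=Thresholds)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry.to_dict(),
            "thresholds": self.thresholds.to_dict(),
            "dataset": self.dataset.to_dict(),
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        lib = material_library()
        geo = d.get("geometry", {})
        if isinstance(geo, dict):
            geo = dict(geo)
            window = geo.pop("window", "quartz")
            if window not in lib:
                raise ValueError(f"unknown window material {window!r}")
            geo = Geometry(window=lib[window], **geo)
        thr = d.get("thresholds", {})
        if isinstance(thr, dict):
            thr = Thresholds.from_dict(thr)
        ds = d.get("dataset", {})
        if isinstance(ds, dict):
            ds = DatasetConfig.from_dict(ds)
        return cls(geometry=geo, thresholds=thr, dataset=ds,
                   log_level=d.get("log_level", "INFO"))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level of the config must be a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
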