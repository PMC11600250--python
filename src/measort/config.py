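"""Run configuration: one nested, human-editable YAML document.

``RunConfig`` gathers detection, sorter, simulator and calcium
parameters plus the master seed and output directory; it round-trips
through YAML exactly and hashes canonically for run manifests.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .simulate import SimulationConfig
from .sort import NetworkSpec, TrainConfig

__all__ = ["DetectionConfig", "CalciumConfig", "RunConfig"]


@dataclass
class DetectionConfig:
    band_low_hz: float = 300.0
    band_high_hz: float = 3000.0
    threshold_multiplier: float = 5.0
    dead_time_s: float = 0.0015
    pre_points: int = 20
    post_points: int = 44


@dataclass
class CalciumConfig:
    bleach_order: int = 10
    prominence_mult: float = 4.0
    frame_interval_s: float = 0.0125
    align_tolerance_s: float = 1.0


@dataclass
class RunConfig:
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    calcium: CalciumConfig = field(default_factory=CalciumConfig)
    n_clusters: int = 5
    seed: int = 0
    output_dir: str = "measort_run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["network"]["layer_sizes"] = list(d["network"]["layer_sizes"])
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        parts = {
            "detection": DetectionConfig,
            "network": NetworkSpec,
            "training": TrainConfig,
            "simulation": SimulationConfig,
            "calcium": CalciumConfig,
        }
        kwargs = {}
        for key, typ in parts.items():
            if key in d:
                sub = dict(d.pop(key))
                for field_name, value in sub.items():
                    if isinstance(value, list):  # YAML has no tuples
                        sub[field_name] = tuple(value)
                kwargs[key] = typ(**sub)
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
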