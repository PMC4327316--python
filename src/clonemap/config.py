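"""Run configuration: sectioned key-value parameters with strict validation.

A run is fully determined by (config, seed).  Unknown keys are rejected so a
typo cannot silently fall back to a default, and the effective configuration
is echoed into every run report.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["RunConfig", "default_config", "load_config", "apply_overrides"]


def _from_mapping(cls, data: dict, section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return cls(**data)


@dataclass
class GridConfig:
    rows: int = 100
    cols: int = 100
    pitch_um: float = 50.0
    layout: str = "hex"


@dataclass
class PoolConfig:
    n_designs: int = 1000
    length_nt: int = 120
    bias: float = 10.0
    abundance_kind: str = "loguniform"


@dataclass
class SynthesisConfig:
    sub_rate: float = 0.6 / 70.0
    ins_rate: float = 0.2 / 70.0
    del_rate: float = 0.2 / 70.0
    n_molecules: int = 2000


@dataclass
class PyroConfig:
    sub_rate: float = 0.001
    indel_rate: float = 0.004
    multiplier: float = 2.0
    read_sigma: float = 0.6
    quality_jitter: float = 1.5


@dataclass
class PlateConfig:
    occupancy: float = 0.10


@dataclass
class DistortionConfig:
    scale: float = 0.25          # pixels per micrometre
    rotation_deg: float = 1.0
    tx_px: float = 40.0
    ty_px: float = 25.0
    k1: float = 0.0
    k2: float = 0.0
    warp_amplitude_px: float = 6.0
    warp_correlation_um: float = 1500.0


@dataclass
class ImagingConfig:
    render: bool = False          # render/detect path vs direct well-map import
    spot_sigma_px: float = 1.8
    noise_sigma: float = 50.0
    min_separation_fraction: float = 0.6


@dataclass
class MappingConfig:
    nx: int = 8
    ny: int = 6
    overlap_fraction: float = 0.20
    threshold_px: float = 13.5


@dataclass
class SelectionConfig:
    max_edit_distance: int = 15
    min_beads_per_design: int = 1
    n_quality_groups: int = 3
    adaptors: list = field(default_factory=list)


@dataclass
class PlannerConfig:
    ordering: str = "serpentine"
    rate_wells_per_s: float = 2.0


@dataclass
class RunConfig:
    seed: int = 0
    grid: GridConfig = field(default_factory=GridConfig)
    pool: PoolConfig = field(default_factory=PoolConfig)
    synthesis: SynthesisConfig = field(default_factory=SynthesisConfig)
    pyro: PyroConfig = field(default_factory=PyroConfig)
    plate: PlateConfig = field(default_factory=PlateConfig)
    distortion: DistortionConfig = field(default_factory=DistortionConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    mapping: MappingConfig = field(default_factory=MappingConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    planner: PlannerConfig = field(default_factory=PlannerConfig)

    _SECTIONS = {
        "grid": GridConfig, "pool": PoolConfig, "synthesis": SynthesisConfig,
        "pyro": PyroConfig, "plate": PlateConfig, "distortion": DistortionConfig,
        "imaging": ImagingConfig, "mapping": MappingConfig,
        "selection": SelectionConfig, "planner": PlannerConfig,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        seed = data.pop("seed", 0)
        kwargs = {"seed": int(seed)}
        for name, scls in cls._SECTIONS.items():
            section = data.pop(name, {}) or {}
            if not isinstance(section, dict):
                raise ValueError(f"section [{name}] must be a mapping")
            kwargs[name] = _from_mapping(scls, section, name)
        if data:
            raise ValueError(f"unknown config section(s): {sorted(data)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = {"seed": self.seed}
        for name in self._SECTIONS:
            out[name] = dataclasses.asdict(getattr(self, name))
        return out


def default_config(seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.from_dict(data or {})


def apply_overrides(config: RunConfig, overrides) -> RunConfig:
    """Apply ``section.key=value`` strings on top of a config."""
    data = config.to_dict()
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override {item!r} is not of form section.key=value")
        key, value = item.split("=", 1)
        parts = key.split(".")
        if len(parts) == 1 and parts[0] == "seed":
            data["seed"] = int(value)
            continue
        if len(parts) != 2:
            raise ValueError(f"override key {key!r} is not of form section.key")
        section, name = parts
        if section not in data or name not in data[section]:
            raise ValueError(f"unknown config key {key!r}")
        data[section][name] = yaml.safe_load(value)
    return RunConfig.from_dict(data)
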