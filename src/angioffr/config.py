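"""Run configuration: one flat, validated YAML document per run.

Every tunable of the pipeline lives here with its documented default;
unknown keys are rejected so a typo cannot silently fall back to a default.
``load_config(save_config(cfg)) == cfg`` for all valid configs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .flow import HyperemiaModel
from .pressure import FluidProperties

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class FluidSection:
    mu: float = 0.0035   # Pa s
    rho: float = 1050.0  # kg/m^3


@dataclass(frozen=True)
class HyperemiaSection:
    pa_slope: float = 0.90
    pa_intercept: float = 0.0   # mmHg
    flow_factor: float = 2.0
    severity_attenuation: bool = False


@dataclass(frozen=True)
class GeometrySection:
    exclusion_frac: float = 0.10
    entry_frac: float = 0.10
    exit_frac: float = 0.05
    merge_gap_mm: float = 2.0
    resample_step_mm: float = 0.1
    reference_mode: str = "interpolated"  # or "proximal_mean"


@dataclass(frozen=True)
class SegmentationSection:
    search_half_width_px: float = 10.0
    scan_half_width_px: float = 15.0
    max_dropped_frac: float = 0.20


@dataclass(frozen=True)
class StatsSection:
    threshold: float = 0.80
    confidence: float = 0.95


@dataclass(frozen=True)
class RunConfig:
    fluid: FluidSection = field(default_factory=FluidSection)
    hyperemia: HyperemiaSection = field(default_factory=HyperemiaSection)
    geometry: GeometrySection = field(default_factory=GeometrySection)
    segmentation: SegmentationSection = field(default_factory=SegmentationSection)
    stats: StatsSection = field(default_factory=StatsSection)
    kt: float = 1.52
    seed: int = 0

    def __post_init__(self) -> None:
        # delegate numeric validation to the owning domain types
        self.fluid_properties()
        self.hyperemia_model()
        g = self.geometry
        if not (0 < g.entry_frac < 1 and 0 <= g.exit_frac <= g.entry_frac):
            raise ConfigurationError("invalid geometry thresholds")
        if g.resample_step_mm <= 0 or g.merge_gap_mm < 0:
            raise ConfigurationError("invalid geometry steps")
        if g.reference_mode not in ("interpolated", "proximal_mean"):
            raise ConfigurationError("reference_mode must be 'interpolated' or 'proximal_mean'")
        if not (0 < self.stats.threshold < 1) or not (0 < self.stats.confidence < 1):
            raise ConfigurationError("invalid stats section")
        if self.kt <= 0:
            raise ConfigurationError("kt must be positive")

    def fluid_properties(self) -> FluidProperties:
        return FluidProperties(mu=self.fluid.mu, rho=self.fluid.rho)

    def hyperemia_model(self) -> HyperemiaModel:
        h = self.hyperemia
        return HyperemiaModel(
            pa_slope=h.pa_slope,
            pa_intercept=h.pa_intercept,
            flow_factor=h.flow_factor,
            severity_attenuation=h.severity_attenuation,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "fluid": FluidSection,
    "hyperemia": HyperemiaSection,
    "geometry": GeometrySection,
    "segmentation": SegmentationSection,
    "stats": StatsSection,
}


def _build_section(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys under '{path}': {sorted(unknown)}")
    return cls(**data)


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.pop(name, {})
        if not isinstance(section, dict):
            raise ConfigurationError(f"config section '{name}' must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    top_known = {"kt", "seed"}
    unknown = set(data) - top_known
    if unknown:
        raise ConfigurationError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs.update(data)
    return RunConfig(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
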