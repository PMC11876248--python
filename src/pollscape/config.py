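"""YAML configuration with strict validation.

Unknown keys are rejected so a typo in a factorial design cannot silently
fall back to a default.  The effective (defaulted) configuration is echoed
to the output directory by the CLI, recording exactly what was run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any

import yaml

from .experiments import DEFAULT_HABITAT_PERCENTAGES, DEFAULT_HAZARD_LEVELS, ExperimentDesign
from .scenario import Parcel, ScenarioSpec
from .synthesis import ConfigurationError, GeneratorSettings

__all__ = ["RunConfig", "load_config", "dump_config", "design_from_config", "scenario_from_config"]


@dataclass
class KernelConfig:
    foraging_radius_m: float = 500.0
    decay_length_m: float | None = None  # None -> radius / 2
    boundary_mode: str = "renormalize"
    include_focal_cell: bool = True


@dataclass
class LandscapeConfig:
    extent_m: list[float] = field(default_factory=lambda: [2000.0, 2000.0])
    cell_size_m: float = 10.0


@dataclass
class CandidateConfig:
    coarse_cell_size_m: float = 10.0
    autocorrelation_length_m: float = 0.0


@dataclass
class DesignConfig:
    habitat_fractions: list[float] = field(
        default_factory=lambda: list(DEFAULT_HABITAT_PERCENTAGES)
    )
    hazard_levels: list[float] = field(default_factory=lambda: list(DEFAULT_HAZARD_LEVELS))
    n_levels: int = 5
    n_reps: int = 50
    base_seed: int = 0
    reps_for_estimation: int = 10
    candidates: list[CandidateConfig] | None = None


@dataclass
class ParcelConfig:
    x0: float = 0.0
    y0: float = 0.0
    x1: float = 0.0
    y1: float = 0.0
    class_name: str = "OTHER"


@dataclass
class ScenarioConfig:
    extent_m: list[float] = field(default_factory=lambda: [3000.0, 3000.0])
    cell_size_m: float = 10.0
    fruit_hazard: float = 75.0
    foraging_ranges_m: list[float] = field(default_factory=lambda: [400.0, 1000.0])
    parcels: list[ParcelConfig] | None = None  # None -> packaged default layout


@dataclass
class RunConfig:
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    kernel: KernelConfig = field(default_factory=KernelConfig)
    design: DesignConfig = field(default_factory=DesignConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)


def _build(cls, data: Any, path: str):
    if data is None:
        return cls()
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: expected a mapping, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ConfigurationError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = known[name]
        if name == "candidates" and value is not None:
            value = [_build(CandidateConfig, v, f"{path}.candidates[{i}]") for i, v in enumerate(value)]
        elif name == "parcels" and value is not None:
            value = [_build(ParcelConfig, v, f"{path}.parcels[{i}]") for i, v in enumerate(value)]
        elif is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _build(f.type, value, f"{path}.{name}")
        kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML config; ``None`` yields all defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a mapping")
    unknown = set(raw) - {"landscape", "kernel", "design", "scenario"}
    if unknown:
        raise ConfigurationError(f"unknown top-level config keys {sorted(unknown)}")
    return RunConfig(
        landscape=_build(LandscapeConfig, raw.get("landscape"), "landscape"),
        kernel=_build(KernelConfig, raw.get("kernel"), "kernel"),
        design=_build(DesignConfig, raw.get("design"), "design"),
        scenario=_build(ScenarioConfig, raw.get("scenario"), "scenario"),
    )


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Echo the effective configuration as YAML."""
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=False))


def design_from_config(config: RunConfig, n_reps: int | None = None, seed: int | None = None) -> ExperimentDesign:
    d = config.design
    candidates = None
    if d.candidates is not None:
        candidates = tuple(
            GeneratorSettings(
                habitat_fraction=0.5,
                coarse_cell_size=c.coarse_cell_size_m,
                autocorrelation_length=c.autocorrelation_length_m,
            )
            for c in d.candidates
        )
    return ExperimentDesign(
        habitat_percentages=tuple(d.habitat_fractions),
        hazard_levels=tuple(d.hazard_levels),
        n_levels=d.n_levels,
        n_reps=n_reps if n_reps is not None else d.n_reps,
        base_seed=seed if seed is not None else d.base_seed,
        extent=tuple(config.landscape.extent_m),
        cell_size=config.landscape.cell_size_m,
        foraging_radius=config.kernel.foraging_radius_m,
        decay_length=config.kernel.decay_length_m,
        boundary_mode=config.kernel.boundary_mode,
        candidates=candidates,
        reps_for_estimation=d.reps_for_estimation,
    )


def scenario_from_config(config: RunConfig) -> ScenarioSpec:
    s = config.scenario
    if s.parcels is None:
        from .scenario import default_scenario

        base = default_scenario()
        parcels = base.parcels
    else:
        parcels = tuple(Parcel(p.x0, p.y0, p.x1, p.y1, p.class_name) for p in s.parcels)
    return ScenarioSpec(
        extent=tuple(s.extent_m),
        cell_size=s.cell_size_m,
        parcels=parcels,
        fruit_hazard=s.fruit_hazard,
        foraging_ranges=tuple(s.foraging_ranges_m),
    )
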