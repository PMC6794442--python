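"""Structured run configuration: strict loading, defaults, round-tripping.

A :class:`RunConfig` gathers every tunable of the pipeline — sensor
geometry, scene defaults, the preset monocular front end, the
genetic-algorithm block, and probe settings — under a single master seed.
Files are JSON or YAML; omitted fields fall back to the model defaults and
unknown keys are rejected with an error naming the key.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evolution import EvolutionConfig
from .frontend import CENTER_SIGMOID, OUTPUT_SIGMOID, SURROUND_SIGMOID
from .geometry import SensorGeometry
from .sigmoid import SigmoidParams
from .stimuli import FIGURE_LUMINANCE, SceneSpec


class ConfigError(ValueError):
    """Raised for unknown keys, type mismatches or out-of-range values."""


@dataclass(frozen=True)
class FrontendConfig:
    """Preset (non-evolving) monocular parameters."""

    center: SigmoidParams = CENTER_SIGMOID
    surround: SigmoidParams = SURROUND_SIGMOID
    output: SigmoidParams = OUTPUT_SIGMOID
    figure_luminance: float = FIGURE_LUMINANCE


@dataclass(frozen=True)
class ProbeConfig:
    """Probe grids and tolerances."""

    grid_step: float = 0.01
    max_probe: float = 0.18
    limit_tolerance: float = 0.02
    odi_sweep_halfwidth: float = 0.09
    odi_sweep_points: int = 25
    negligible_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.grid_step <= 0 or self.max_probe <= 0:
            raise ConfigError("probe grid settings must be positive")
        if self.limit_tolerance < 0 or self.negligible_threshold < 0:
            raise ConfigError("tolerances must be non-negative")


@dataclass(frozen=True)
class RunConfig:
    geometry: SensorGeometry = field(default_factory=SensorGeometry)
    scene: SceneSpec = field(default_factory=SceneSpec)
    frontend: FrontendConfig = field(default_factory=FrontendConfig)
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    probes: ProbeConfig = field(default_factory=ProbeConfig)
    master_seed: int = 0


_OPTIONAL_FLOATS = {"reference_offset", "reference_disparity"}


def _build(cls, data: dict, prefix: str):
    """Recursively populate a (possibly nested) dataclass, strictly."""
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping for {prefix or cls.__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        where = prefix or cls.__name__
        raise ConfigError(f"unknown key {sorted(unknown)[0]!r} in {where}")
    kwargs = {}
    for name, value in data.items():
        path = f"{prefix}.{name}" if prefix else name
        if isinstance(value, dict):
            sub = _FIELD_CLASSES.get((cls, name))
            if sub is None:
                raise ConfigError(f"{path} does not take a mapping")
            kwargs[name] = _build(sub, value, path)
        else:
            if value is None and name not in _OPTIONAL_FLOATS:
                raise ConfigError(f"{path} may not be null")
            if isinstance(value, bool) or isinstance(value, (list, tuple)):
                raise ConfigError(f"{path}: unsupported value type {type(value).__name__}")
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in {prefix or cls.__name__}: {exc}") from exc


_FIELD_CLASSES = {
    (RunConfig, "geometry"): SensorGeometry,
    (RunConfig, "scene"): SceneSpec,
    (RunConfig, "frontend"): FrontendConfig,
    (RunConfig, "evolution"): EvolutionConfig,
    (RunConfig, "probes"): ProbeConfig,
    (FrontendConfig, "center"): SigmoidParams,
    (FrontendConfig, "surround"): SigmoidParams,
    (FrontendConfig, "output"): SigmoidParams,
}


def load_config(path) -> RunConfig:
    """Load and validate a RunConfig from a JSON or YAML file.

    An empty file yields the full default configuration.  Every unknown key,
    type mismatch or out-of-range value raises :class:`ConfigError` naming
    the offending key.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    return _build(RunConfig, data, "")


def config_to_dict(config: RunConfig) -> dict:
    return dataclasses.asdict(config)


def save_config(config: RunConfig, path) -> None:
    """Write a config so that load_config returns an identical object."""
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=1))
    else:
        path.write_text(yaml.safe_dump(data))
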