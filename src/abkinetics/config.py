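"""Run configuration: YAML loading with strict validation.

Configs use experimental conventions at the boundary — concentrations in
µM — and are converted to the internal mM exactly once, here. Unknown keys
are rejected so silent typos cannot change a run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .fitting import GridSpec
from .ode_engine import SolverSettings
from .reaction_models import KineticParams, ModelConfig
from .synthetic_data import ExperimentDesign

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


def _build_dataclass(cls, section: dict[str, Any], where: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")
    for key in ("protofibril_uM_list", "forward_values", "reverse_values",
                "refine_mantissas", "refine_decades"):
        if key in section and isinstance(section[key], list):
            section[key] = tuple(section[key])
    try:
        return cls(**section)
    except (TypeError, ValueError) as err:
        raise ConfigError(f"invalid {where}: {err}") from err


@dataclass
class RunConfig:
    """Validated configuration for one command invocation."""

    model: str = "simple"  # simple | complete | lateral | pathway
    params: KineticParams = field(default_factory=KineticParams)
    model_config: ModelConfig = field(default_factory=ModelConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    solver: SolverSettings = field(default_factory=SolverSettings)
    target_pair: str = "elongation"
    monomer_uM: float = 30.0
    protofibril_uM: float = 4.0
    duration_min: float = 1.0
    seed: int = 0
    log_level: str = "INFO"

    _SECTIONS = {
        "params": KineticParams,
        "model_config": ModelConfig,
        "grid": GridSpec,
        "design": ExperimentDesign,
        "solver": SolverSettings,
    }
    _SCALARS = {
        "model": str,
        "target_pair": str,
        "monomer_uM": float,
        "protofibril_uM": float,
        "duration_min": float,
        "seed": int,
        "log_level": str,
    }

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        unknown = set(raw) - set(cls._SECTIONS) - set(cls._SCALARS)
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in raw:
                if not isinstance(raw[name], dict):
                    raise ConfigError(f"section {name!r} must be a mapping")
                kwargs[name] = _build_dataclass(section_cls, dict(raw[name]), name)
        for name, typ in cls._SCALARS.items():
            if name in raw:
                kwargs[name] = typ(raw[name])
        cfg = cls(**kwargs)
        if cfg.model not in ("simple", "complete", "lateral", "pathway"):
            raise ConfigError(f"unknown model {cfg.model!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)
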