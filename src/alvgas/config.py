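"""Run configuration: JSON/YAML loading with strict schema checking.

A config file is a flat mapping whose keys are the alveolus parameter
field names (missing keys fall back to the healthy defaults), plus the
optional reserved sections ``binding`` (field overrides for
:class:`~alvgas.binding.BindingParameters`), ``lung``
(:class:`~alvgas.parameters.LungScale` overrides), ``n_sections``,
``output`` and ``log_level``.  Unknown keys are rejected with their
paths so typos cannot silently revert a parameter to its default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .binding import BindingParameters
from .parameters import AlveolusParameters, LungScale, validate_parameters

__all__ = ["RunConfig", "OutputOptions", "load_config", "ConfigError", "dump_config"]


class ConfigError(ValueError):
    """Schema violation in a configuration file."""


@dataclass(frozen=True)
class OutputOptions:
    directory: str = "."
    formats: tuple[str, ...] = ("csv",)
    pressure_unit: str = "mmHg"


@dataclass(frozen=True)
class RunConfig:
    parameters: AlveolusParameters = field(default_factory=AlveolusParameters)
    binding: BindingParameters = field(default_factory=BindingParameters)
    lung: LungScale = field(default_factory=LungScale)
    n_sections: int = 100
    output: OutputOptions = field(default_factory=OutputOptions)
    log_level: str = "INFO"


def _build(cls, data: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} under {path!r}; known: {sorted(known)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid values under {path!r}: {exc}") from exc


_RESERVED = {"binding", "lung", "n_sections", "output", "log_level"}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML run configuration.

    An empty file yields the full defaults.  Parameter-range violations
    are aggregated into one error message.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")

    param_keys = {f.name for f in dataclasses.fields(AlveolusParameters)}
    unknown = set(data) - param_keys - _RESERVED
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)}; parameter keys: {sorted(param_keys)}; "
            f"reserved sections: {sorted(_RESERVED)}")

    params = _build(AlveolusParameters,
                    {k: v for k, v in data.items() if k in param_keys}, "parameters")
    violations = [
        v for v in validate_parameters(params)
        # the no-perfusion limit (blood volume exactly 0) is legal input
        if not (v.field == "blood_volume" and params.blood_volume == 0.0)
    ]
    if violations:
        raise ConfigError("parameter range violation(s): " + "; ".join(map(str, violations)))

    cfg = RunConfig(
        parameters=params,
        binding=_build(BindingParameters, dict(data.get("binding", {})), "binding"),
        lung=_build(LungScale, dict(data.get("lung", {})), "lung"),
        n_sections=int(data.get("n_sections", 100)),
        output=_build(OutputOptions, dict(data.get("output", {})), "output"),
        log_level=str(data.get("log_level", "INFO")),
    )
    if cfg.n_sections < 2:
        raise ConfigError("n_sections must be >= 2")
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Echo the resolved configuration (for provenance of an output dir)."""
    payload = dataclasses.asdict(cfg.parameters)
    payload["n_sections"] = cfg.n_sections
    payload["binding"] = dataclasses.asdict(cfg.binding)
    payload["lung"] = dataclasses.asdict(cfg.lung)
    payload["output"] = dataclasses.asdict(cfg.output)
    payload["log_level"] = cfg.log_level
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
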