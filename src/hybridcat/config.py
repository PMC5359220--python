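"""YAML/JSON configuration files mapped onto :class:`RunConfig`.

A config file is a flat-ish mapping with optional ``design``, ``memory``,
``timing`` and ``utility`` sub-mappings; unknown keys are rejected so typos
fail loudly. The resolved configuration (including the seed actually used)
can be echoed back to disk next to simulation outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .control import UtilityParams
from .design import DesignSpec
from .experiment import RunConfig
from .memory import MemoryParams
from .routes import TimingParams

__all__ = ["load_config", "dump_config"]

_SECTIONS = {
    "design": DesignSpec,
    "memory": MemoryParams,
    "timing": TimingParams,
    "utility": UtilityParams,
}


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown keys {sorted(unknown)}")
    for key, value in data.items():
        if isinstance(value, list):
            data[key] = tuple(value)
    return cls(**data)


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Read a YAML (or JSON) run configuration; keyword overrides win."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        if section in raw:
            kwargs[section] = _build(cls, dict(raw.pop(section)))
    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_names
    if unknown:
        raise ValueError(f"{path}: unknown keys {sorted(unknown)}")
    kwargs.update(raw)
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Echo a fully-resolved configuration (seed included) to YAML or JSON."""
    payload = dataclasses.asdict(config)
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(payload, indent=1, default=list))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
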