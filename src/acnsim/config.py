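"""YAML run configuration tying all parameter groups together.

Every default equals the study's stated value where one exists (potential
strengths alpha=100, beta=-20, gamma=-1; capillary intensity and width
ranges; SNR range 1-10 dB; speckle width multiplier 8; threshold multiplier
c=2; 128 x 128 x 64 volumes with ~20-layer sub-volumes and 3-6 end points).
Unknown keys and invalid values are rejected with the offending key named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .frames import FragmentationParams, RenderParams
from .pathways import PotentialParams
from .unet import TrainConfig, UNetSpec
from .volumes import DatasetSpec

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config"]


class ConfigError(ValueError):
    """Configuration validation error; the message names the offending key."""


@dataclass(frozen=True)
class RunConfig:
    potential: PotentialParams = field(default_factory=PotentialParams)
    render: RenderParams = field(default_factory=RenderParams)
    fragmentation: FragmentationParams = field(default_factory=FragmentationParams)
    dataset: DatasetSpec = field(default_factory=DatasetSpec)
    unet: UNetSpec = field(default_factory=UNetSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    threshold_c: float = 2.0
    n_layers: int = 20
    seed: int = 0
    out_dir: str = "acn_output"


_TUPLE_FIELDS = {"input_dims"}


def _from_dict(cls, d: dict, path: str):
    if not isinstance(d, dict):
        raise ConfigError(f"section '{path or cls.__name__}' must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(d) - names
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown key '{path + key}'")
    kwargs: dict[str, Any] = {}
    for f in dataclasses.fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        if dataclasses.is_dataclass(f.type) or (
            isinstance(f.default_factory, type)
            and dataclasses.is_dataclass(f.default_factory)
        ):
            sub = f.default_factory  # nested dataclass type
            kwargs[f.name] = _from_dict(sub, v, f"{path}{f.name}.")
        else:
            if f.name in _TUPLE_FIELDS and isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"in section '{path or 'root'}': {exc}") from exc


def config_from_dict(d: dict) -> RunConfig:
    return _from_dict(RunConfig, d, "")


def config_to_dict(cfg) -> dict:
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if dataclasses.is_dataclass(v):
            out[f.name] = config_to_dict(v)
        elif isinstance(v, tuple):
            out[f.name] = list(v)
        else:
            out[f.name] = v
    return out


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    return config_from_dict(raw)


def dump_config(cfg: RunConfig, path: str | Path | None = None) -> str:
    """Serialise a configuration back to YAML (lossless round trip)."""
    text = yaml.safe_dump(config_to_dict(cfg), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
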