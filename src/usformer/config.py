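"""Run configuration: strict YAML parsing into the dataclass hierarchy.

Unknown keys are rejected (naming the offending key) so a typo can never
silently fall back to a default. An empty file yields the full default
configuration: lambda = 1, lr = 0.001, 200 epochs, threshold 0.5, channels
16/32/64/128/256.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .augment import AugmentConfig
from .net import UsformerConfig
from .objective import LossConfig
from .phantoms import PhantomSpec
from .train import TrainConfig

__all__ = ["RunConfig", "parse_config", "config_to_dict"]


@dataclass
class PathsConfig:
    train_dir: str = ""
    val_dir: str = ""
    test_dir: str = ""
    out_dir: str = "runs"


@dataclass
class RunConfig:
    network: UsformerConfig = field(default_factory=UsformerConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    paths: PathsConfig = field(default_factory=PathsConfig)
    seed: int = 0


class ConfigError(ValueError):
    pass


def _coerce(value, typ):
    # tuples arrive from YAML as lists
    if isinstance(value, list):
        return tuple(value)
    return value


def _build(cls, payload: dict, prefix: str = ""):
    if payload is None:
        payload = {}
    if not isinstance(payload, dict):
        raise ConfigError(f"section '{prefix or cls.__name__}' must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(payload) - set(known)
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown configuration key: '{prefix}{key}'")
    kwargs = {}
    for name, value in payload.items():
        f = known[name]
        sub = _field_dataclass(f)
        if sub is not None:
            kwargs[name] = _build(sub, value, prefix=f"{prefix}{name}.")
        else:
            kwargs[name] = _coerce(value, f.type)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration in section '{prefix or 'root'}': {exc}")


def _field_dataclass(f):
    if is_dataclass(f.type):
        return f.type
    if f.default_factory is not dataclasses.MISSING and is_dataclass(f.default_factory):
        return f.default_factory
    return None


def parse_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; missing/empty file sections use defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    payload = yaml.safe_load(path.read_text()) or {}
    return _build(RunConfig, payload)


def config_to_dict(cfg) -> dict:
    """Serialize any config dataclass to plain YAML-safe types."""
    d = dataclasses.asdict(cfg)

    def clean(v):
        if isinstance(v, tuple):
            return [clean(x) for x in v]
        if isinstance(v, dict):
            return {k: clean(x) for k, x in v.items()}
        return v

    return clean(d)
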