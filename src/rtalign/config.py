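"""Run configuration: one YAML file drives the whole pipeline.

Unknown keys are rejected so typos fail loudly instead of silently falling
back to defaults. Every default is documented on the dataclass fields.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .io import FilterConfig


@dataclass
class ModelConfig:
    tolerance: float = 1e-7  # relative objective change to declare convergence
    max_iterations: int = 20000
    segmented: bool = True  # two-segment transform (False = single slope)


@dataclass
class BootstrapConfig:
    n_replicates: int = 100
    # seed defaults to the run-level seed when omitted
    seed: int | None = None


@dataclass
class QvalueConfig:
    enabled: bool = True
    scope: str = "targets"  # or "all" to pool decoys into the q-value ranking


@dataclass
class QuantConfig:
    enabled: bool = False
    empty_channels: tuple[str, ...] = ()
    channel_prefix: str = "Reporter intensity corrected"
    pep_threshold: float = 0.01
    min_psms: int = 3


@dataclass
class RunConfig:
    """Top-level configuration for a pipeline run."""

    inputs: tuple[str, ...] = ()
    output_dir: str = "rtalign_out"
    seed: int = 0
    verbosity: str = "info"
    filters: FilterConfig = field(default_factory=FilterConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    qvalues: QvalueConfig = field(default_factory=QvalueConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)

    def bootstrap_seed(self) -> int:
        return self.seed if self.bootstrap.seed is None else self.bootstrap.seed


def _build(cls, doc: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(doc) - set(fields)
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s) {sorted(unknown)} under {path!r}"
        )
    kwargs = {}
    for name, value in doc.items():
        f = fields[name]
        sub_default = (
            f.default_factory() if f.default_factory is not dataclasses.MISSING else None
        )
        if dataclasses.is_dataclass(sub_default):
            if value is not None and not isinstance(value, dict):
                raise ConfigurationError(f"{path}.{name} must be a mapping")
            kwargs[name] = _build(type(sub_default), value or {}, f"{path}.{name}")
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    doc = yaml.safe_load(path.read_text()) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration root must be a mapping")
    return _build(RunConfig, doc, "<root>")


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)
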