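"""Run configuration: validated YAML/JSON experiment descriptors."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .parameters import GridSpec, ModelParameters

__all__ = ["RunConfig", "load_config", "dump_config"]

EXPERIMENT_KINDS = ("simulate", "sweep", "perturb", "mpsa", "blotcalc")

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParameters)}
_GRID_FIELDS = {f.name for f in dataclasses.fields(GridSpec)}

#: allowed argument keys per experiment kind
_EXPERIMENT_ARGS = {
    "simulate": {"t_end", "cue_side"},
    "sweep": {"amp_min", "amp_max", "amp_step", "t_end"},
    "perturb": {"species", "level", "rate"},
    "mpsa": {"n_samples", "range_lo", "range_hi", "n_dummies", "t_end"},
    "blotcalc": {"input_csv"},
}


class ConfigError(ValueError):
    """A configuration key, type or value is invalid."""


@dataclass
class RunConfig:
    """Validated configuration of one experiment run.

    Omitted model parameters and grid settings fall back to the
    baseline values; unknown keys are rejected rather than ignored.
    """

    experiment: str = "simulate"
    experiment_args: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    grid: dict = field(default_factory=dict)
    output_dir: str = "abpolar-run"
    seed: int = 0
    snapshot_stride: float = 1.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENT_KINDS:
            raise ConfigError(
                f"experiment must be one of {EXPERIMENT_KINDS}, "
                f"got {self.experiment!r}")
        unknown = set(self.model) - _PARAM_FIELDS
        if unknown:
            raise ConfigError(f"unknown model parameters: {sorted(unknown)}")
        unknown = set(self.grid) - _GRID_FIELDS
        if unknown:
            raise ConfigError(f"unknown grid settings: {sorted(unknown)}")
        allowed = _EXPERIMENT_ARGS[self.experiment]
        unknown = set(self.experiment_args) - allowed
        if unknown:
            raise ConfigError(
                f"unknown arguments for {self.experiment}: {sorted(unknown)}")
        # delegate value validation to the frozen dataclasses
        try:
            self.parameters()
            self.gridspec()
        except (ValueError, TypeError) as exc:
            raise ConfigError(str(exc)) from exc

    def parameters(self) -> ModelParameters:
        return ModelParameters(**self.model)

    def gridspec(self) -> GridSpec:
        return GridSpec(**self.grid)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML (or JSON) run configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    return RunConfig(**data)


def dump_config(config: RunConfig, path) -> None:
    """Write the resolved configuration back out (round-trips via load)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
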