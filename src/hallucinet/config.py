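"""Run configuration: YAML/JSON loading, validation, round-tripping.

A RunConfig either names a preset or spells out explicit AM parameters,
plus input image path(s), an output directory, a weights source and a
global seed. Unknown keys are rejected so typos fail loudly rather than
silently running defaults.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import yaml

from .am_engine import AMConfig, config_from_preset
from .presets import PRESET_NAMES, make_preset

DEFAULT_WEIGHTS = "fixture:default"


class ConfigError(ValueError):
    """Invalid or unparseable run configuration."""


@dataclass
class RunConfig:
    input: list[str]
    out: str
    preset: str | None = None
    am_type: str | None = None
    error_function: str | None = None
    terminal_layer: str | None = None
    target_index: int | None = None
    iterations: int = 1000
    snapshot_iters: list[int] = field(default_factory=lambda: [10, 50, 100, 1000])
    step_size: float | None = None
    latent_clamp: bool = True
    inversion_steps: int = 0
    deep_dream_initial_mask: bool = False
    weights: str = DEFAULT_WEIGHTS
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.input, str):
            self.input = [self.input]
        if not self.input:
            raise ConfigError("input: at least one image path required")
        if self.preset is None and self.am_type is None:
            raise ConfigError("either preset or explicit am_type must be given")
        if self.preset is not None and self.preset not in PRESET_NAMES:
            raise ConfigError(
                f"preset: unknown preset {self.preset!r}; known: {PRESET_NAMES}")
        try:
            self.to_am_config()
        except ConfigError:
            raise
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def to_am_config(self) -> AMConfig:
        """Materialise the AMConfig this run will execute (preset defaults
        merged with explicit overrides)."""
        if self.preset is not None:
            return config_from_preset(
                make_preset(self.preset), seed=self.seed,
                iterations=self.iterations,
                snapshot_iters=tuple(self.snapshot_iters),
                target_index=self.target_index,
                step_size=self.step_size)
        return AMConfig(
            am_type=self.am_type,
            error_function=self.error_function or "winner_take_all",
            terminal_layer=self.terminal_layer or "fc_top",
            target_index=self.target_index,
            iterations=self.iterations,
            snapshot_iters=tuple(self.snapshot_iters),
            step_size=self.step_size,
            latent_clamp=self.latent_clamp,
            inversion_steps=self.inversion_steps,
            deep_dream_initial_mask=self.deep_dream_initial_mask,
            seed=self.seed)


_FIELDS = set(RunConfig.__dataclass_fields__)


def load_run_config(path: str | os.PathLike) -> RunConfig:
    """Load and validate a YAML or JSON run configuration file."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh)  # YAML is a superset of JSON
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    unknown = set(raw) - _FIELDS
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def save_run_config(config: RunConfig, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)


def write_json(obj, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
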