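"""Layered run configuration: documented defaults, optional TOML config
file, CLI flag overrides (flags win)."""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass

__all__ = ["RunConfig", "resolve_config", "ConfigError"]


class ConfigError(ValueError):
    """Unknown key or out-of-range value in a configuration layer."""


@dataclass(frozen=True)
class RunConfig:
    # tolerances (Da)
    precursor_tol: float = 0.02
    frag_tol: float = 0.02
    offset_tol: float = 0.01
    # analog search
    analog_window: float = 200.0
    analog_min_score: float = 0.8
    analog_min_peaks: int = 6
    # two-tier library search
    search_min_score: float = 0.7
    search_min_peaks: int = 2
    accept_min_score: float = 0.9
    accept_min_peaks: int = 5
    # preprocessing
    precursor_exclusion: float = 17.0
    window: float = 50.0
    top_k: int = 6
    # curation
    library_score_thr: float = 0.7
    library_peaks_thr: int = 6
    max_frequency: float = 0.5
    dedup_min_score: float = 0.95
    # ion-form classification
    r2_threshold: float = 0.9
    # exposure readout
    blank_fold: float = 3.0
    noise_floor_value: float = 1e4
    # misc
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("precursor_tol", "frag_tol", "offset_tol", "analog_window"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in (
            "analog_min_score", "search_min_score", "accept_min_score",
            "dedup_min_score", "max_frequency", "r2_threshold",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name in ("analog_min_peaks", "search_min_peaks", "accept_min_peaks",
                     "library_peaks_thr", "top_k"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.blank_fold <= 0:
            raise ConfigError("blank_fold must be positive")
        if self.noise_floor_value < 0:
            raise ConfigError("noise_floor_value must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELDS = {f.name: f.type for f in dataclasses.fields(RunConfig)}


def resolve_config(
    defaults: RunConfig | None = None,
    config_file: str | None = None,
    cli_flags: dict | None = None,
) -> RunConfig:
    """Merge configuration layers with precedence flags > file > defaults.

    Unknown keys raise :class:`ConfigError` naming the key; range checks run
    on the merged result.
    """
    merged = (defaults or RunConfig()).to_dict()
    layers = []
    if config_file is not None:
        with open(config_file, "rb") as handle:
            layers.append(tomllib.load(handle))
    if cli_flags:
        layers.append({k: v for k, v in cli_flags.items() if v is not None})
    for layer in layers:
        for key, value in layer.items():
            if key not in _FIELDS:
                raise ConfigError(f"unknown configuration key: {key!r}")
            merged[key] = value
    return RunConfig(**merged)
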