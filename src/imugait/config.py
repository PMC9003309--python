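"""YAML run configuration for the pipeline CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .errors import ConfigError
from .estimator import NoiseConfig


@dataclass
class RunConfig:
    """Validated pipeline configuration with defaults filled in."""

    calibration_data: str | None = None
    walking_data: str | None = None
    reference_angles: str | None = None  # CSV prefix of reference angle files
    output_dir: str = "."
    seed: int = 0
    keyframe_rate: float = 20.0
    n_windows: int = 60
    m_star: float = 0.05  # deg/s
    drift_correction: bool = True
    prior_inflation: float = 4.0
    noise: NoiseConfig = field(default_factory=NoiseConfig)

    def __post_init__(self) -> None:
        if self.m_star <= 0:
            raise ConfigError("m_star must be positive (deg/s)")
        if self.n_windows < 1:
            raise ConfigError("n_windows must be >= 1")
        if self.keyframe_rate <= 0:
            raise ConfigError("keyframe_rate must be positive (Hz)")


def validate_config(path) -> RunConfig:
    """Load and schema-check a YAML config; unknown keys are rejected."""
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    known = {f.name for f in fields(RunConfig)}
    noise_known = {f.name for f in fields(NoiseConfig)}
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown config key {key!r}")
    noise_raw = raw.pop("noise", {}) or {}
    if not isinstance(noise_raw, dict):
        raise ConfigError("'noise' must be a mapping of sigma values")
    for key in noise_raw:
        if key not in noise_known:
            raise ConfigError(f"unknown noise config key {key!r}")
    try:
        noise = NoiseConfig(**noise_raw)
        return RunConfig(noise=noise, **raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
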