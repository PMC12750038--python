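"""Run configuration: a validated bag of paths, metric parameters and seeds."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    refs: str | None = None
    subs: str | None = None
    manifest: str | None = None
    out: str = "ligeval_out"
    seed: int = 0
    site_cutoff: float = 4.0
    inclusion_radius: float = 4.0
    thresholds: list[float] = field(default_factory=lambda: [0.5, 1.0, 2.0, 4.0])
    success_cutoff: float = 2.5
    automorphism_cap: int = 10_000
    include_nonpolymer: bool = True
    sigmas: list[float] = field(default_factory=lambda: [0.66, 2.0])
    resamples: int = 1000
    rt: float = 0.6
    blacklist: list[str] = field(default_factory=list)
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.site_cutoff <= 0 or self.inclusion_radius <= 0:
            raise ConfigError("cutoffs must be positive")
        if list(self.thresholds) != sorted(self.thresholds) or not self.thresholds:
            raise ConfigError("thresholds must be a non-empty ascending list")
        if self.resamples < 1:
            raise ConfigError("resamples must be >= 1")
        if any(s < 0 for s in self.sigmas):
            raise ConfigError("sigmas must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config file, apply keyword overrides, reject unknown keys."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc
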