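"""Run configuration: defaults, validation, YAML/JSON round-trip, seeding.

All randomness in a run flows from a single root seed through named
sub-streams (one per stage: selection/mutation, environment draws, null
models, genome initialisation), so stages can be replayed independently and
whole runs are reproducible from (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import yaml

from .dynamics import STANDARD_ENV, EnvironmentParams
from .evolution import (DEFAULT_FLUCTUATION, DEFAULT_LEVEL_FACTORS,
                        DEFAULT_N_LEVELS, ExperimentProtocol)
from .mutation import MutationRates

__all__ = ["RunConfig", "ConfigError", "load_config", "dump_config",
           "config_to_dict", "config_from_dict", "stream_rng"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Complete specification of an evolutionary run."""
    seed: int = 0
    population_size: int = 1024
    max_generations: int = 15000
    high_fitness_cutoff: float = 0.85
    post_cutoff_delay: int = 1000
    snapshot_interval: int = 100
    rates: MutationRates = field(default_factory=MutationRates)
    environment: EnvironmentParams = STANDARD_ENV
    level_factors: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LEVEL_FACTORS))
    fluctuation: Tuple[float, float] = DEFAULT_FLUCTUATION
    fluctuation_levels: Optional[int] = DEFAULT_N_LEVELS
    genome_size_range: Tuple[int, int] = (30, 60)
    category_proportions: Tuple[float, float, float] = (0.4, 0.4, 0.2)
    motif_length: int = 5
    alphabet_size: int = 2
    output_dir: str = "runs"

    def protocol(self) -> ExperimentProtocol:
        return ExperimentProtocol(
            high_fitness_cutoff=self.high_fitness_cutoff,
            post_cutoff_delay=self.post_cutoff_delay,
            max_generations=self.max_generations)


_STREAMS = ("evolution", "environment", "null_model", "init", "analysis")


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Named random sub-stream derived from the root seed."""
    if stream not in _STREAMS:
        raise ConfigError(f"unknown rng stream {stream!r}; one of {_STREAMS}")
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(_STREAMS.index(stream),)))


def _validate(cfg: RunConfig) -> RunConfig:
    if cfg.population_size < 1:
        raise ConfigError("population_size must be >= 1")
    if not 0.0 < cfg.high_fitness_cutoff <= 1.0:
        raise ConfigError("high_fitness_cutoff must be in (0, 1]")
    if cfg.max_generations < 0 or cfg.post_cutoff_delay < 0:
        raise ConfigError("generation counts must be >= 0")
    if not 0.0 <= cfg.rates.max_segment_fraction <= 1.0:
        raise ConfigError("rates.max_segment_fraction must be in [0, 1]")
    if cfg.fluctuation[0] <= 0 or cfg.fluctuation[1] < cfg.fluctuation[0]:
        raise ConfigError("fluctuation must be a positive (low, high) range")
    if cfg.genome_size_range[0] < 1 or cfg.genome_size_range[1] < cfg.genome_size_range[0]:
        raise ConfigError("genome_size_range must be a valid (min, max)")
    if abs(sum(cfg.category_proportions) - 1.0) > 1e-9:
        raise ConfigError("category_proportions must sum to 1")
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    d = {
        "seed": cfg.seed,
        "population_size": cfg.population_size,
        "max_generations": cfg.max_generations,
        "high_fitness_cutoff": cfg.high_fitness_cutoff,
        "post_cutoff_delay": cfg.post_cutoff_delay,
        "snapshot_interval": cfg.snapshot_interval,
        "rates": dataclasses.asdict(cfg.rates),
        "environment": {k: getattr(cfg.environment, k) for k in (
            "A_ext", "permeability", "degradation", "conversion_rate",
            "target_A", "target_X")},
        "level_factors": {k: list(v) for k, v in cfg.level_factors.items()},
        "fluctuation": list(cfg.fluctuation),
        "fluctuation_levels": cfg.fluctuation_levels,
        "genome_size_range": list(cfg.genome_size_range),
        "category_proportions": list(cfg.category_proportions),
        "motif_length": cfg.motif_length,
        "alphabet_size": cfg.alphabet_size,
        "output_dir": cfg.output_dir,
    }
    return d


_TOP_KEYS = set(config_to_dict(RunConfig()))


def config_from_dict(data: Optional[dict]) -> RunConfig:
    data = dict(data or {})
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kw: dict = {}
    try:
        if "rates" in data:
            kw["rates"] = MutationRates(**data.pop("rates"))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid key 'rates': {exc}") from exc
    try:
        if "environment" in data:
            kw["environment"] = EnvironmentParams(**data.pop("environment"))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid key 'environment': {exc}") from exc
    if "level_factors" in data:
        kw["level_factors"] = {k: tuple(v)
                               for k, v in data.pop("level_factors").items()}
    for name in ("fluctuation", "genome_size_range", "category_proportions"):
        if name in data:
            kw[name] = tuple(data.pop(name))
    kw.update(data)
    try:
        cfg = RunConfig(**kw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return _validate(cfg)


def load_config(path) -> RunConfig:
    """Read YAML (JSON accepted); an empty file yields the full defaults."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path) as fh:
            text = fh.read()
    data = yaml.safe_load(text) if text.strip() else {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return config_from_dict(data)


def dump_config(cfg: RunConfig, path) -> None:
    text = yaml.safe_dump(config_to_dict(cfg), sort_keys=True)
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)
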