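"""Run configuration and run report for the island grouping GA."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError
from .objectives import OBJECTIVES

__all__ = ["GGAConfig", "RunReport"]

_DISTANCES = ("euclidean", "mahalanobis", "gk", "afc")


@dataclass
class GGAConfig:
    """All evolutionary-search parameters.

    The defaults are the reference configuration used throughout: population
    of 20 per island, 4 islands, 400 generations, crossover probability
    decaying 0.8 -> 0.6, mutation probability growing 0.05 -> 0.1, local
    search probability decaying 0.1 -> 0.05, migration probability 0.03 and
    fuzzifier alpha = 2. Cluster-count bounds and local-search/numerical
    knobs are package choices exposed here.
    """

    population_size: int = 20
    n_islands: int = 4
    total_generations: int = 400
    p_crossover_initial: float = 0.8
    p_crossover_final: float = 0.6
    p_mutation_initial: float = 0.05
    p_mutation_final: float = 0.1
    p_local_initial: float = 0.1
    p_local_final: float = 0.05
    p_migration: float = 0.03
    fuzzifier: float = 2.0
    k_min: int = 2
    k_init_max: int = 10
    k_max: int = 15
    local_search_trials: int = 20
    covariance_regularizer: float = 1e-8
    objective: str = "mdb"
    distance: str = "euclidean"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigError("population_size must be >= 2")
        if self.n_islands < 1:
            raise ConfigError("n_islands must be >= 1")
        if self.total_generations < 1:
            raise ConfigError("total_generations must be >= 1")
        if not 2 <= self.k_min <= self.k_init_max <= self.k_max:
            raise ConfigError("need 2 <= k_min <= k_init_max <= k_max")
        if self.fuzzifier <= 1:
            raise ConfigError("fuzzifier must exceed 1")
        for name in (
            "p_crossover_initial",
            "p_crossover_final",
            "p_mutation_initial",
            "p_mutation_final",
            "p_local_initial",
            "p_local_final",
            "p_migration",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.objective not in OBJECTIVES:
            raise ConfigError(f"objective must be one of {OBJECTIVES}")
        if self.distance not in _DISTANCES:
            raise ConfigError(f"distance must be one of {_DISTANCES}")
        if self.local_search_trials < 0:
            raise ConfigError("local_search_trials must be >= 0")

    @classmethod
    def from_file(cls, path: str, **overrides) -> "GGAConfig":
        """Load a flat YAML/JSON mapping; keyword overrides win over the file."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunReport:
    """Outcome of one evolutionary run.

    ``best`` is the winning chromosome; ``trace`` has one row per generation:
    (generation index, best objective so far, cluster count of the incumbent
    best). The best objective always equals the minimum over the trace.
    """

    best: object
    best_objective: float
    best_n_clusters: int
    trace: list[tuple[int, float, int]]
    seed: int
    config: dict = field(default_factory=dict)

    def to_json(self, path: str) -> None:
        payload = {
            "best_objective": self.best_objective,
            "best_n_clusters": self.best_n_clusters,
            "seed": self.seed,
            "config": self.config,
            "trace": [
                {"generation": g, "best_objective": o, "best_k": k}
                for g, o, k in self.trace
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
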