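"""Replicated benchmark protocol: medians of (k, Rand) over seeded runs.

One benchmark dataset is generated per study from the master seed, and the
(stochastic) algorithm is rerun on it with one derived run seed per
replicate; medians and modes therefore estimate the single-realization
quantity a one-shot run reports, with the run-to-run search variability
averaged out. The whole study is a pure function of (experiment, algorithm
settings, master seed, replicate count).
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .benchmarks import gen_experiment
from .chromosome import defuzzify
from .config import GGAConfig
from .engine import run_island_gga
from .evaluation import rand_index
from .fcm import fcm_fit

__all__ = ["gga_replicates", "fcm_replicates", "median_rand", "modal_k"]


def _study_seeds(seed: int, replicates: int) -> tuple[int, list[int]]:
    """One data seed plus ``replicates`` run seeds, all below 2**31."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(replicates + 1)
    states = [
        int(c.generate_state(1, dtype=np.uint32)[0] >> np.uint32(1)) for c in children
    ]
    return states[0], states[1:]


def gga_replicates(
    experiment: int,
    objective: str,
    distance: str,
    replicates: int = 5,
    seed: int = 0,
    **config_overrides,
) -> list[tuple[int, float]]:
    """Run the island GGA ``replicates`` times; return (k, Rand) per run."""
    data_seed, run_seeds = _study_seeds(seed, replicates)
    data = gen_experiment(experiment, seed=data_seed)
    out = []
    for run_seed in run_seeds:
        config = GGAConfig(
            objective=objective, distance=distance, seed=run_seed, **config_overrides
        )
        report = run_island_gga(data, config)
        labels = defuzzify(report.best)
        out.append((report.best_n_clusters, rand_index(labels, data.labels)))
    return out


def fcm_replicates(
    experiment: int,
    n_clusters: int,
    replicates: int = 5,
    seed: int = 0,
    fuzzifier: float = 2.0,
    n_init: int = 10,
) -> list[tuple[int, float]]:
    """Run fuzzy C-means ``replicates`` times; return (C, Rand) per run."""
    data_seed, run_seeds = _study_seeds(seed, replicates)
    data = gen_experiment(experiment, seed=data_seed)
    out = []
    for run_seed in run_seeds:
        chrom = fcm_fit(
            data, n_clusters, fuzzifier=fuzzifier, n_init=n_init, rng=run_seed
        )
        out.append((n_clusters, rand_index(defuzzify(chrom), data.labels)))
    return out


def median_rand(results: list[tuple[int, float]]) -> float:
    return float(np.median([r for _, r in results]))


def modal_k(results: list[tuple[int, float]]) -> int:
    counts = Counter(k for k, _ in results)
    top = max(counts.values())
    return min(k for k, c in counts.items() if c == top)
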