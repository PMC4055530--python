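"""Cluster validity indices used as minimized objective functions.

Four internal (unsupervised) indices drive the evolutionary search:

- ``fsse``: fuzzy sum of squared errors, sum_i sum_j u_ij^alpha d2(x_j, mu_i).
- ``xb``:   Xie-Beni, fSSE / (N * min pairwise centroid separation).
- ``fs``:   Fukuyama-Sugeno, fSSE minus the membership-weighted separation of
            centroids from their unweighted average mu*; may be negative.
- ``mdb``:  a fuzzy adaptation of the Davies-Bouldin index — for each cluster
            the worst ratio of summed membership-weighted scatters to
            centroid separation, averaged over clusters. Metric-aware: under
            covariance-based metrics each cluster measures with its own M_i
            and pairwise separation takes the min over the two clusters'
            metrics.

Small values of every index correspond to compact, well-separated partitions;
all four are minimized. In the crisp, Euclidean limit ``mdb`` reduces to the
classical Davies-Bouldin index.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .chromosome import FuzzyChromosome
from .distances import (
    ClusterModel,
    DistanceSpec,
    build_cluster_model,
    centroid_separation_sq,
    sq_distances,
)
from .errors import ConfigError, DegeneratePartitionError, ValidationError

__all__ = [
    "OBJECTIVES",
    "fsse",
    "xb_index",
    "fs_index",
    "mdb_index",
    "evaluate_objective",
    "rank_fitness",
    "RankFitness",
]

OBJECTIVES = ("fsse", "xb", "fs", "mdb")

#: Pairwise centroid separations below this are treated as coincident.
SEPARATION_TOL = 1e-12


def _pair_separation(model: ClusterModel, spec: DistanceSpec) -> np.ndarray:
    """Symmetric (k, k) separation: min over the two clusters' own metrics."""
    A = centroid_separation_sq(model, spec)
    return A if not spec.needs_covariance else np.minimum(A, A.T)


def _min_separation(model: ClusterModel, spec: DistanceSpec) -> float:
    sep = _pair_separation(model, spec)
    k = sep.shape[0]
    off = sep[~np.eye(k, dtype=bool)]
    m = float(off.min())
    if m < SEPARATION_TOL:
        raise DegeneratePartitionError("coincident centroids (separation ~ 0)")
    return m


def _weights_and_d2(dataset, chromosome, model, spec, alpha):
    W = chromosome.membership**alpha
    d2 = sq_distances(dataset.points, model, spec)
    return W, d2


def fsse(dataset, chromosome, model, spec, fuzzifier: float = 2.0) -> float:
    """Fuzzy sum of squared errors under the active metric."""
    W, d2 = _weights_and_d2(dataset, chromosome, model, spec, fuzzifier)
    return float((W * d2).sum())


def xb_index(dataset, chromosome, model, spec, fuzzifier: float = 2.0) -> float:
    """Xie-Beni index: fSSE over N times the minimum centroid separation."""
    if chromosome.n_clusters < 2:
        raise DegeneratePartitionError("Xie-Beni needs at least 2 clusters")
    num = fsse(dataset, chromosome, model, spec, fuzzifier)
    return num / (dataset.n_points * _min_separation(model, spec))


def fs_index(dataset, chromosome, model, spec, fuzzifier: float = 2.0) -> float:
    """Fukuyama-Sugeno index: compactness minus separation from mu*."""
    W, d2 = _weights_and_d2(dataset, chromosome, model, spec, fuzzifier)
    term1 = float((W * d2).sum())
    gdiff = model.centroids - model.global_centroid
    if spec.needs_covariance:
        d2g = np.einsum("id,ide,ie->i", gdiff, model.metrics, gdiff)
    else:
        d2g = np.einsum("id,id->i", gdiff, gdiff)
    term2 = float(W.sum(axis=1) @ d2g)
    return term1 - term2


def mdb_index(dataset, chromosome, model, spec, fuzzifier: float = 2.0) -> float:
    """Fuzzy modified Davies-Bouldin index (metric-aware, minimized).

    Per-cluster scatter is the *mass-normalized* membership-weighted mean
    squared distance S_i = sum_t u_it^alpha d2(x_t, mu_i) / sum_t u_it^alpha,
    the fuzzy analogue of the average within-cluster dispersion in the
    classical Davies-Bouldin index (and the same normalization the fuzzy
    covariance uses). Without that normalization the index rewards splitting
    large clusters and its minimum over k drifts upward on unbalanced data.
    """
    if chromosome.n_clusters < 2:
        raise DegeneratePartitionError("MDB needs at least 2 clusters")
    W, d2 = _weights_and_d2(dataset, chromosome, model, spec, fuzzifier)
    intra = (W * d2).sum(axis=1) / W.sum(axis=1)  # normalized scatter S_i
    sep = _pair_separation(model, spec)
    k = sep.shape[0]
    off = ~np.eye(k, dtype=bool)
    if sep[off].min() < SEPARATION_TOL:
        raise DegeneratePartitionError("coincident centroids (separation ~ 0)")
    np.fill_diagonal(sep, 1.0)  # diagonal never enters the max below
    ratio = (intra[:, None] + intra[None, :]) / sep
    ratio[~off] = -np.inf
    return float(ratio.max(axis=1).mean())


_DISPATCH = {"fsse": fsse, "xb": xb_index, "fs": fs_index, "mdb": mdb_index}


def evaluate_objective(
    dataset,
    chromosome: FuzzyChromosome,
    objective: str,
    spec: DistanceSpec,
    fuzzifier: float = 2.0,
    model: ClusterModel | None = None,
) -> float:
    """Build the cluster model (unless given) and evaluate one named index."""
    if objective not in _DISPATCH:
        raise ConfigError(
            f"unknown objective {objective!r}; expected one of {OBJECTIVES}"
        )
    if model is None:
        model = build_cluster_model(
            dataset.points, chromosome.membership, fuzzifier, spec
        )
    return _DISPATCH[objective](dataset, chromosome, model, spec, fuzzifier)


class RankFitness(NamedTuple):
    """Rank-based selection weights.

    ``fitness`` is aligned with the input objective vector; ``intervals`` are
    the cumulative roulette breakpoints in rank order (best individual first,
    last breakpoint exactly 1); ``order`` maps rank position -> individual
    index, so a draw landing in interval r selects individual order[r].
    """

    fitness: np.ndarray
    intervals: np.ndarray
    order: np.ndarray


def rank_fitness(objective_values, minimize: bool = True) -> RankFitness:
    """Static rank-based fitness f_i = 2 R_i / (xi (xi + 1)).

    The best individual receives rank xi, the worst rank 1; the fitness
    values sum to one and define a roulette wheel whose first interval
    belongs to the best individual. Ties in objective value are broken by
    individual index (stable sort), so selection is deterministic given the
    random draws.
    """
    values = np.asarray(objective_values, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValidationError("objective_values must be a nonempty 1-D vector")
    xi = values.size
    order = np.argsort(values if minimize else -values, kind="stable")
    ranks_sorted = np.arange(xi, 0, -1)  # best -> xi, worst -> 1
    f_sorted = 2.0 * ranks_sorted / (xi * (xi + 1))
    fitness = np.empty(xi)
    fitness[order] = f_sorted
    intervals = np.cumsum(f_sorted)
    intervals[-1] = 1.0
    return RankFitness(fitness=fitness, intervals=intervals, order=order)
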