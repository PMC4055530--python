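"""Fuzzy cluster models and squared point-to-centroid metrics.

Four metrics are supported, all expressed as quadratic forms
d2(x, mu_i) = (x - mu_i) M_i (x - mu_i)^T with a per-cluster metric matrix:

- ``euclidean``:    M_i = I
- ``mahalanobis``:  M_i = Sigma_i^{-1}, with Sigma_i the *fuzzy* covariance
                    (membership-weighted scatter with weights u^alpha)
- ``gk``:           M_i = |Sigma_i|^{1/d} Sigma_i^{-1}  (Gustafson-Kessel;
                    determinant-normalized, so elliptical clusters of any
                    orientation but unit volume)
- ``afc``:          M_i = lambda_i Sigma_i^{-1}, with lambda_i an adaptive
                    volume term (default: smallest eigenvalue of Sigma_i),
                    allowing clusters of different volumes.

Covariances are regularized with eps * trace(Sigma)/d on the diagonal before
inversion, which keeps every metric positive definite even for tiny or
collinear clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ConfigError, DegeneratePartitionError

__all__ = [
    "DistanceSpec",
    "ClusterModel",
    "fuzzy_centroids",
    "fuzzy_covariance",
    "build_cluster_model",
    "sq_distance",
    "sq_distances",
    "centroid_separation_sq",
    "smallest_eigenvalue",
]

_KINDS = ("euclidean", "mahalanobis", "gk", "afc")


def smallest_eigenvalue(covariances: np.ndarray) -> np.ndarray:
    """Default adaptive volume term: smallest eigenvalue of each Sigma_i."""
    return np.linalg.eigvalsh(covariances)[:, 0]


@dataclass(frozen=True)
class DistanceSpec:
    """Metric choice plus numerical knobs.

    ``afc_lambda`` maps the stacked (k, d, d) covariances to the length-k
    adaptive terms; the default uses the smallest eigenvalue of Sigma_i
    (equivalently 1/largest eigenvalue of Sigma_i^{-1}).
    """

    kind: str = "euclidean"
    regularizer: float = 1e-8
    afc_lambda: Callable[[np.ndarray], np.ndarray] = field(
        default=smallest_eigenvalue
    )

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigError(
                f"unknown distance kind {self.kind!r}; expected one of {_KINDS}"
            )
        if self.regularizer < 0:
            raise ConfigError("regularizer must be nonnegative")

    @property
    def needs_covariance(self) -> bool:
        return self.kind != "euclidean"


@dataclass
class ClusterModel:
    """Per-cluster geometry: centroids, covariances, metric matrices.

    ``metrics`` holds the full quadratic-form matrices M_i described in the
    module docstring (None for the Euclidean metric). ``global_centroid`` is
    the unweighted mean of the k centroids.
    """

    centroids: np.ndarray
    covariances: np.ndarray | None = None
    metrics: np.ndarray | None = None
    lambdas: np.ndarray | None = None

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    @property
    def global_centroid(self) -> np.ndarray:
        return self.centroids.mean(axis=0)


def fuzzy_centroids(dataset, chromosome, fuzzifier: float = 2.0) -> np.ndarray:
    """Membership-weighted cluster centroids, weights u_ij^alpha."""
    return _centroids(dataset.points, chromosome.membership, fuzzifier)


def _centroids(X: np.ndarray, U: np.ndarray, alpha: float) -> np.ndarray:
    W = U**alpha
    wsum = W.sum(axis=1)
    if wsum.min() <= 0.0:
        raise DegeneratePartitionError("cluster with zero total membership weight")
    return (W @ X) / wsum[:, None]


def fuzzy_covariance(
    dataset,
    chromosome,
    centroids: np.ndarray,
    fuzzifier: float = 2.0,
    regularizer: float = 1e-8,
) -> np.ndarray:
    """Stacked (k, d, d) fuzzy covariances, regularized to positive definite."""
    return _covariances(
        dataset.points, chromosome.membership, centroids, fuzzifier, regularizer
    )


def _covariances(
    X: np.ndarray,
    U: np.ndarray,
    centroids: np.ndarray,
    alpha: float,
    eps: float,
) -> np.ndarray:
    W = U**alpha
    wsum = W.sum(axis=1)
    diff = X[None, :, :] - centroids[:, None, :]  # (k, N, d)
    cov = np.einsum("kn,knd,kne->kde", W, diff, diff, optimize=True)
    cov /= wsum[:, None, None]
    d = X.shape[1]
    tr = np.trace(cov, axis1=1, axis2=2)
    bump = np.where(tr > 0.0, eps * tr / d, eps)
    cov[:, np.arange(d), np.arange(d)] += bump[:, None]
    return cov


def build_cluster_model(
    X: np.ndarray,
    U: np.ndarray,
    fuzzifier: float,
    spec: DistanceSpec,
) -> ClusterModel:
    """Compute centroids and, for covariance-based metrics, the M_i matrices."""
    centroids = _centroids(X, U, fuzzifier)
    if not spec.needs_covariance:
        return ClusterModel(centroids=centroids)
    cov = _covariances(X, U, centroids, fuzzifier, spec.regularizer)
    inv = np.linalg.inv(cov)
    if spec.kind == "mahalanobis":
        metrics = inv
        lambdas = None
    elif spec.kind == "gk":
        d = X.shape[1]
        det = np.linalg.det(cov)
        metrics = det[:, None, None] ** (1.0 / d) * inv
        lambdas = None
    else:  # afc
        lambdas = spec.afc_lambda(cov)
        metrics = lambdas[:, None, None] * inv
    return ClusterModel(
        centroids=centroids, covariances=cov, metrics=metrics, lambdas=lambdas
    )


def sq_distances(X: np.ndarray, model: ClusterModel, spec: DistanceSpec) -> np.ndarray:
    """(k, N) matrix of squared distances from each centroid to each point."""
    diff = X[None, :, :] - model.centroids[:, None, :]
    if not spec.needs_covariance:
        return np.einsum("knd,knd->kn", diff, diff)
    if model.metrics is None:
        raise ConfigError(f"model lacks metric matrices required by {spec.kind!r}")
    return np.einsum("knd,kde,kne->kn", diff, model.metrics, diff, optimize=True)


def sq_distance(
    point: np.ndarray,
    cluster_index: int,
    model: ClusterModel,
    spec: DistanceSpec,
) -> float:
    """Squared distance from one point to one cluster under the active metric."""
    diff = np.asarray(point, dtype=float) - model.centroids[cluster_index]
    if not spec.needs_covariance:
        return float(diff @ diff)
    if model.metrics is None:
        raise ConfigError(f"model lacks metric matrices required by {spec.kind!r}")
    return float(diff @ model.metrics[cluster_index] @ diff)


def centroid_separation_sq(model: ClusterModel, spec: DistanceSpec) -> np.ndarray:
    """(k, k) separations between centroids under each *row* cluster's metric.

    Entry [i, j] is d2_i(mu_i, mu_j), the squared distance measured with
    cluster i's own metric. For the Euclidean metric the matrix is symmetric.
    Validity indices that need a single pairwise separation take
    min([i, j], [j, i]), mirroring the Gustafson-Kessel convention.
    """
    cd = model.centroids[:, None, :] - model.centroids[None, :, :]
    if not spec.needs_covariance:
        return np.einsum("ijd,ijd->ij", cd, cd)
    return np.einsum("ijd,ide,ije->ij", cd, model.metrics, cd, optimize=True)
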