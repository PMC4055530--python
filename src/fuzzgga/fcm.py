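"""Fuzzy C-means baseline (alternating optimization, Euclidean metric)."""

from __future__ import annotations

import numpy as np

from .chromosome import FuzzyChromosome
from .dataset import Dataset
from .errors import ValidationError

__all__ = ["fcm_fit", "memberships_from_sq_distances"]


def memberships_from_sq_distances(d2: np.ndarray, alpha: float) -> np.ndarray:
    """Columnwise-optimal memberships u_ij = 1 / sum_l (d_ij/d_lj)^(2/(alpha-1)).

    ``d2`` is the (k, N) matrix of squared point-to-centroid distances. This
    is the unique minimizer of sum_i u_ij^alpha d2_ij per column subject to
    the column summing to 1. A point coincident with one or more centroids
    gets its mass split equally over the coincident clusters (crisp-tie
    convention).
    """
    zero = d2 <= 1e-300
    any_zero = zero.any(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-1.0 / (alpha - 1.0))
        U = inv / inv.sum(axis=0)
    if any_zero.any():
        cols = np.nonzero(any_zero)[0]
        U[:, cols] = zero[:, cols] / zero[:, cols].sum(axis=0)
    return U


def _memberships(X: np.ndarray, centroids: np.ndarray, alpha: float) -> np.ndarray:
    diff = X[None, :, :] - centroids[:, None, :]
    d2 = np.einsum("knd,knd->kn", diff, diff)  # (C, N)
    return memberships_from_sq_distances(d2, alpha)


def fcm_fit(
    dataset: Dataset,
    n_clusters: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    n_init: int = 10,
    rng: np.random.Generator | int | None = None,
) -> FuzzyChromosome:
    """Fit fuzzy C-means, returning the best of ``n_init`` random starts.

    Each start initializes centroids at ``n_clusters`` distinct random
    observations and alternates centroid/membership updates until the
    largest membership change falls below ``tol`` or ``max_iter`` sweeps.
    Starts are compared by the fuzzy sum of squared errors; within a start
    that criterion is non-increasing across iterations.
    """
    X = dataset.points
    N = dataset.n_points
    if not 2 <= n_clusters <= N:
        raise ValidationError(f"need 2 <= C <= N, got C={n_clusters}, N={N}")
    if fuzzifier <= 1:
        raise ValidationError("fuzzifier must exceed 1")
    rng = np.random.default_rng(rng)

    best_U, best_sse = None, np.inf
    for _ in range(n_init):
        centroids = X[rng.choice(N, size=n_clusters, replace=False)].copy()
        U = _memberships(X, centroids, fuzzifier)
        for _ in range(max_iter):
            W = U**fuzzifier
            centroids = (W @ X) / W.sum(axis=1)[:, None]
            U_new = _memberships(X, centroids, fuzzifier)
            shift = np.abs(U_new - U).max()
            U = U_new
            if shift < tol:
                break
        W = U**fuzzifier
        diff = X[None, :, :] - centroids[:, None, :]
        sse = float((W * np.einsum("knd,knd->kn", diff, diff)).sum())
        if sse < best_sse:
            best_U, best_sse = U, sse
    return FuzzyChromosome(best_U)
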