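"""Two-section grouping chromosome for fuzzy partitions.

An individual is a pair [U | g]: the *element section* U is a k x N fuzzy
partition matrix (columns sum to one, no empty cluster row), and the *group
section* g is the list of cluster tags. Tags are cosmetic after repair
(always 1..k); they exist so group-level crossover can track which clusters
were inherited from which parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegeneratePartitionError, ValidationError

__all__ = [
    "FuzzyChromosome",
    "defuzzify",
    "repair_chromosome",
    "EMPTY_CLUSTER_TOL",
]

#: A cluster is "empty" when its membership row sums below this.
EMPTY_CLUSTER_TOL = 1e-9

#: Column sums must match 1 to within this for a chromosome to be valid.
COLUMN_SUM_TOL = 1e-9


@dataclass
class FuzzyChromosome:
    """A candidate fuzzy partition: k x N membership matrix plus group tags."""

    membership: np.ndarray
    groups: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=float)
        if self.groups is None:
            self.groups = np.arange(1, self.membership.shape[0] + 1)
        else:
            self.groups = np.asarray(self.groups, dtype=int)

    @property
    def n_clusters(self) -> int:
        return self.membership.shape[0]

    @property
    def n_points(self) -> int:
        return self.membership.shape[1]

    def copy(self) -> "FuzzyChromosome":
        return FuzzyChromosome(self.membership.copy(), self.groups.copy())

    def validate(self) -> None:
        """Raise unless the fuzzy-partition constraints hold.

        Columns must sum to 1 (within 1e-9), entries lie in [0, 1], every
        cluster row has positive mass below N, k >= 2, and group tags are
        consecutive from 1.
        """
        U = self.membership
        k, n = U.shape
        if k < 2:
            raise DegeneratePartitionError(f"partition has {k} < 2 clusters")
        if U.min() < -COLUMN_SUM_TOL or U.max() > 1 + COLUMN_SUM_TOL:
            raise ValidationError("membership entries outside [0, 1]")
        col = U.sum(axis=0)
        if np.abs(col - 1.0).max() > COLUMN_SUM_TOL:
            raise ValidationError("membership columns do not sum to 1")
        row = U.sum(axis=1)
        if row.min() <= 0.0 or row.max() >= n:
            raise ValidationError("empty or all-absorbing cluster row")
        if not np.array_equal(self.groups, np.arange(1, k + 1)):
            raise ValidationError("group tags are not consecutive 1..k")


def defuzzify(chromosome: FuzzyChromosome) -> np.ndarray:
    """Crisp labels (1-based) by maximal membership, ties to the lowest index."""
    return np.argmax(chromosome.membership, axis=0) + 1


def repair_chromosome(
    chromosome: FuzzyChromosome,
    tolerance: float = EMPTY_CLUSTER_TOL,
    dataset=None,
    spec=None,
    fuzzifier: float = 2.0,
    crisp_empty: bool = False,
) -> FuzzyChromosome:
    """Remove empty clusters, renumber group tags 1..k, renormalize columns.

    Clusters whose membership row sums below ``tolerance`` are deleted and the
    surviving tags renumbered consecutively from 1. Each column is rescaled to
    sum exactly 1. A column left with no mass (all of it sat in deleted
    clusters) is reassigned crisply to the nearest surviving centroid; when
    ``dataset`` is given, "nearest" is measured under the active distance
    ``spec`` (Euclidean if spec is None), otherwise the cluster with the
    largest total mass is used as a last resort.

    With ``crisp_empty=True`` a cluster is additionally considered empty when
    no observation belongs to it maximally (it wins no defuzzified argmax);
    this is the emptiness notion the evolutionary loop uses, so a chromosome
    cannot accumulate near-zero-mass "shadow" clusters that a 1/k-averaged
    validity index would otherwise reward.

    Idempotent: repairing a repaired chromosome is the identity.
    """
    U = np.asarray(chromosome.membership, dtype=float)
    if U.min() < 0:
        raise ValidationError("membership entries must be nonnegative")
    row_mass = U.sum(axis=1)
    keep = row_mass >= tolerance
    if crisp_empty:
        wins = np.zeros(U.shape[0], dtype=bool)
        wins[np.unique(np.argmax(U, axis=0))] = True
        keep &= wins
    if keep.sum() < 2:
        raise DegeneratePartitionError(
            f"only {int(keep.sum())} non-empty clusters remain after repair"
        )
    U = U[keep]

    col = U.sum(axis=0)
    orphan = col < EMPTY_CLUSTER_TOL
    if orphan.any():
        U = U.copy()
        if dataset is not None:
            from .distances import DistanceSpec, build_cluster_model, sq_distances

            dspec = spec if spec is not None else DistanceSpec("euclidean")
            ok = ~orphan
            W = U[:, ok] / U[:, ok].sum(axis=0, keepdims=True)
            model = build_cluster_model(
                dataset.points[ok], W, fuzzifier, dspec
            )
            d2 = sq_distances(dataset.points[orphan], model, dspec)  # k x n_orphan
            nearest = np.argmin(d2, axis=0)
        else:
            nearest = np.full(int(orphan.sum()), int(np.argmax(U.sum(axis=1))))
        U[:, orphan] = 0.0
        U[nearest, np.nonzero(orphan)[0]] = 1.0
        col = U.sum(axis=0)

    U = U / col
    return FuzzyChromosome(U, np.arange(1, U.shape[0] + 1))
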