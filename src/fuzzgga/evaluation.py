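"""Supervised evaluation of crisp partitions by pair counting (Rand index).

Over all N(N-1)/2 unordered pairs of observations, each partition decides
"same cluster" or "different cluster"; the Rand index is the fraction of
pairs on which the predicted partition agrees with the ground truth. It is
invariant to relabeling of either side. Fuzzy partitions are defuzzified
before evaluation; pair counting is never applied to soft memberships.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["PairConfusion", "pair_confusion", "rand_index"]


@dataclass(frozen=True)
class PairConfusion:
    """Pair-level confusion counts.

    TP: same cluster in both partitions; FP: same in predicted only;
    TN: different in both; FN: same in truth only. The four counts always
    sum to N(N-1)/2.
    """

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def _check(predicted, truth) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(predicted).ravel()
    t = np.asarray(truth).ravel()
    if p.shape != t.shape:
        raise ValidationError(f"label lengths differ: {p.size} vs {t.size}")
    if p.size < 2:
        raise ValidationError("need at least 2 observations")
    return p, t


def pair_confusion(predicted_labels, true_labels) -> PairConfusion:
    """Count agreement over all unordered observation pairs.

    Uses the contingency-table identities (sums of C(n, 2) over cells,
    rows and columns) rather than an explicit pair loop, so it is exact
    and O(N + cells).
    """
    p, t = _check(predicted_labels, true_labels)
    n = p.size
    _, pi = np.unique(p, return_inverse=True)
    _, ti = np.unique(t, return_inverse=True)
    cont = np.zeros((pi.max() + 1, ti.max() + 1), dtype=np.int64)
    np.add.at(cont, (pi, ti), 1)

    def pairs(x):
        return int((x.astype(np.int64) * (x - 1) // 2).sum())

    total = n * (n - 1) // 2
    tp = pairs(cont.ravel())
    same_pred = pairs(cont.sum(axis=1))
    same_true = pairs(cont.sum(axis=0))
    fp = same_pred - tp
    fn = same_true - tp
    tn = total - tp - fp - fn
    return PairConfusion(TP=tp, FP=fp, TN=tn, FN=fn)


def rand_index(predicted_labels, true_labels) -> float:
    """Fraction of correct same/different decisions: (TP + TN) / all pairs."""
    c = pair_confusion(predicted_labels, true_labels)
    return (c.TP + c.TN) / c.total
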