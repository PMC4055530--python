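"""Feature-table container and delimited-text I/O.

A dataset is an N x d matrix of real feature values, optionally paired with
integer ground-truth labels (used only for supervised evaluation, never by
the clustering itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = ["Dataset", "read_dataset", "write_partition"]


@dataclass(frozen=True)
class Dataset:
    """N observations in d dimensions, with optional true labels and names.

    Parameters
    ----------
    points
        Real feature matrix of shape (N, d); every entry must be finite.
    labels
        Optional integer class identifiers of length N (ground truth).
    ids
        Optional observation names of length N.
    """

    points: np.ndarray
    labels: np.ndarray | None = None
    ids: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2:
            raise ValidationError(f"points must be 2-D, got shape {pts.shape}")
        if pts.shape[0] < 2:
            raise ValidationError(f"need at least 2 observations, got {pts.shape[0]}")
        if pts.shape[1] < 1:
            raise ValidationError("need at least 1 feature")
        if not np.isfinite(pts).all():
            raise ValidationError("points contains non-finite values")
        object.__setattr__(self, "points", pts)
        if self.labels is not None:
            lab = np.asarray(self.labels, dtype=int)
            if lab.shape != (pts.shape[0],):
                raise ValidationError(
                    f"labels length {lab.shape} does not match N={pts.shape[0]}"
                )
            object.__setattr__(self, "labels", lab)
        if self.ids is not None and len(self.ids) != pts.shape[0]:
            raise ValidationError("ids length does not match N")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def n_features(self) -> int:
        return self.points.shape[1]


def read_dataset(
    path: str,
    label_column: str | None = None,
    delimiter: str = ",",
) -> Dataset:
    """Read a delimited feature table (header row required) into a Dataset.

    Non-label columns must be numeric; the optional ``label_column`` is split
    out as ground-truth labels. Row order is preserved.
    """
    try:
        frame = pd.read_csv(path, sep=delimiter)
    except FileNotFoundError as exc:
        raise ValidationError(f"input file not found: {path}") from exc

    labels = None
    if label_column is not None:
        if label_column not in frame.columns:
            raise ValidationError(f"label column {label_column!r} not in header")
        labels = frame[label_column].to_numpy()
        frame = frame.drop(columns=[label_column])

    for col in frame.columns:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        if coerced.isna().any() and not frame[col].isna().any():
            row = int(coerced.isna().idxmax())
            raise ParseError(
                f"non-numeric value {frame[col][row]!r} in column {col!r}, row {row}"
            )
        frame[col] = coerced
    if frame.isna().any().any():
        raise ParseError("feature table contains missing values")

    return Dataset(points=frame.to_numpy(dtype=float), labels=labels)


def write_partition(chromosome, dataset: Dataset, path: str) -> None:
    """Write one row per observation: id, crisp label, then k membership columns.

    Membership values are written with 17 significant digits so a read-back
    reproduces the partition matrix to full double precision.
    """
    from .chromosome import defuzzify

    U = chromosome.membership
    if U.shape[1] != dataset.n_points:
        raise ValidationError(
            f"chromosome covers {U.shape[1]} observations, dataset has "
            f"{dataset.n_points}"
        )
    ids = dataset.ids if dataset.ids is not None else list(range(dataset.n_points))
    frame = pd.DataFrame({"id": ids, "label": defuzzify(chromosome)})
    for i in range(U.shape[0]):
        frame[f"cluster_{i + 1}"] = U[i]
    frame.to_csv(path, index=False, float_format="%.17g")
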