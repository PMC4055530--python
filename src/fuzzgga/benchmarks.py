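"""Seeded Gaussian-mixture benchmark generators.

Three two-dimensional scenarios of increasing difficulty are built in:

1. *Spherical*: 300 points from 8 equiprobable isotropic Gaussians
   (sigma = 0.35 per axis) on a grid of nearby means — many compact,
   partially overlapping round clusters.
2. *Unbalanced*: 400 points from 3 axis-aligned Gaussians with class
   probabilities (0.5, 0.33, 0.17) and unequal per-axis scales.
3. *Heterogeneous*: 300 points from 6 classes mixing correlated,
   anti-correlated, tiny and large covariances — clusters differing in
   orientation and volume, where metric choice matters.

Each observation's class is drawn independently from the class
probabilities (multinomial sampling, so realized class sizes fluctuate),
then its coordinates from that class's Gaussian. Generators are pure
functions of their parameters and seed. A synthetic glyph generator is also
provided: three jittered line-segment strokes forming a capital "A", a
stand-in fixture for stroke-segmentation experiments.
"""

from __future__ import annotations

import numpy as np

from .dataset import Dataset
from .errors import ConfigError, ValidationError

__all__ = ["gen_gaussian_mixture", "gen_experiment", "gen_character_a", "EXPERIMENTS"]


def gen_gaussian_mixture(
    n: int,
    means,
    covariances,
    probabilities,
    seed: int | np.random.Generator | None = None,
) -> Dataset:
    """Sample ``n`` labeled points from a finite Gaussian mixture."""
    means = [np.asarray(m, dtype=float) for m in means]
    covariances = [np.asarray(c, dtype=float) for c in covariances]
    probabilities = np.asarray(probabilities, dtype=float)
    if not (len(means) == len(covariances) == probabilities.size):
        raise ValidationError("means, covariances, probabilities lengths differ")
    if abs(probabilities.sum() - 1.0) > 1e-9 or (probabilities < 0).any():
        raise ValidationError("probabilities must be a simplex vector")
    for c in covariances:
        if np.linalg.eigvalsh(c)[0] <= 0:
            raise ValidationError("covariance matrices must be positive definite")
    rng = np.random.default_rng(seed)
    labels = rng.choice(probabilities.size, size=n, p=probabilities)
    d = means[0].size
    points = np.empty((n, d))
    for cls in range(probabilities.size):
        mask = labels == cls
        if mask.any():
            points[mask] = rng.multivariate_normal(
                means[cls], covariances[cls], size=int(mask.sum())
            )
    return Dataset(points=points, labels=labels + 1)


_SPHERICAL = {
    "n": 300,
    "means": [(-1, 1), (2, -2), (1, 0), (3, -1), (-1, -1), (-1, -3), (1, 2), (3, 1)],
    "covariances": [np.eye(2) * 0.35**2] * 8,
    "probabilities": [1 / 8] * 8,
}

_UNBALANCED = {
    "n": 400,
    "means": [(0, 2), (-1, -1), (2, -1)],
    "covariances": [
        np.diag([1.0**2, 0.8**2]),
        np.diag([0.6**2, 0.4**2]),
        np.diag([0.3**2, 0.5**2]),
    ],
    "probabilities": [0.5, 0.33, 0.17],
}

_HETEROGENEOUS = {
    "n": 300,
    "means": [(-2, -2), (0, -2), (2, -2), (0, 0.5), (-1.5, 2), (2, 2.5)],
    "covariances": [
        np.array([[0.3, 0.28], [0.28, 0.3]]),
        np.eye(2) * 0.02,
        np.array([[0.3, -0.28], [-0.28, 0.3]]),
        np.eye(2) * 0.46,
        np.eye(2) * 0.2,
        np.eye(2) * 0.5,
    ],
    "probabilities": [0.1, 0.1, 0.1, 0.25, 0.25, 0.2],
}

EXPERIMENTS = {1: _SPHERICAL, 2: _UNBALANCED, 3: _HETEROGENEOUS}


def gen_experiment(
    experiment_id: int, seed: int | np.random.Generator | None = None
) -> Dataset:
    """Generate one of the three built-in benchmark scenarios (see module doc)."""
    if experiment_id not in EXPERIMENTS:
        raise ConfigError(f"unknown experiment id {experiment_id!r}; expected 1, 2 or 3")
    return gen_gaussian_mixture(seed=seed, **EXPERIMENTS[experiment_id])


def gen_character_a(
    points_per_stroke: int = 40,
    noise: float = 0.02,
    seed: int | np.random.Generator | None = None,
) -> Dataset:
    """Synthetic glyph: three jittered strokes of a capital "A".

    Two slanted strokes meeting at the apex plus a horizontal bar; points are
    uniform along each segment with isotropic Gaussian jitter of scale
    ``noise``. Labels identify the stroke (1, 2, 3).
    """
    if points_per_stroke < 2:
        raise ValidationError("points_per_stroke must be >= 2")
    rng = np.random.default_rng(seed)
    segments = [
        ((0.0, 0.0), (0.5, 1.0)),  # left stroke
        ((1.0, 0.0), (0.5, 1.0)),  # right stroke
        ((0.25, 0.5), (0.75, 0.5)),  # horizontal bar
    ]
    points, labels = [], []
    for tag, (start, end) in enumerate(segments, start=1):
        t = rng.uniform(0.0, 1.0, size=points_per_stroke)[:, None]
        seg = np.asarray(start) + t * (np.asarray(end) - np.asarray(start))
        seg = seg + rng.normal(scale=noise, size=seg.shape)
        points.append(seg)
        labels.extend([tag] * points_per_stroke)
    return Dataset(points=np.vstack(points), labels=np.array(labels))
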