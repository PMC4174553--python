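"""Synthetic labeled tables with planted symmetric clusters.

The generator emulates the kind of data the point-symmetry distance is
designed for: K clusters of point-symmetric shape (spherical or elliptical
Gaussians, or rings with Gaussian radial jitter) living in a few
*relevant* dimensions, padded with irrelevant *noise* dimensions drawn
uniformly over the relevant data's bounding range so no single feature
dominates the scale.  Cluster centers sit on the relevant coordinate axes
(origin, then s*e0, s*e1, ..., cycling axes with growing radius), where
``s = separation`` is measured in within-cluster standard deviations:
pairwise center distances are always >= s, and — when there are at least as
many clusters as relevant dimensions — every relevant dimension separates
some pair of clusters, so no informative feature is redundant.
``separation >= 6`` means essentially non-overlapping clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tabular_io import Dataset, draw_labeled_idx

SHAPES = ("spherical", "elliptical", "ring")

#: ring geometry: radius in within-cluster-scale units, radial jitter 0.05R
RING_RADIUS = 2.0
RING_JITTER_FRAC = 0.05
#: elliptical clusters: axis standard deviations cycle through this pattern
ELLIPSE_AXES = (1.0, 0.3)


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic mixture."""

    n: int = 300
    k_true: int = 3
    relevant_d: int = 2
    noise_d: int = 3
    shapes: tuple[str, ...] | str = "spherical"
    separation: float = 6.0
    labeled_fraction: float = 0.1
    seed: int = 0
    cluster_sizes: tuple[int, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if self.relevant_d < 1:
            raise ValueError("relevant_d must be >= 1")
        if self.noise_d < 0:
            raise ValueError("noise_d must be >= 0")
        if self.separation <= 0:
            raise ValueError("separation must be > 0")
        if isinstance(self.shapes, str):
            self.shapes = (self.shapes,) * self.k_true
        if len(self.shapes) != self.k_true:
            raise ValueError("need one shape per cluster")
        for s in self.shapes:
            if s not in SHAPES:
                raise ValueError(f"unknown shape {s!r}; choose from {SHAPES}")
        if "ring" in self.shapes and self.relevant_d < 2:
            raise ValueError("ring-shaped clusters need relevant_d >= 2")
        if self.cluster_sizes is None:
            base, extra = divmod(self.n, self.k_true)
            self.cluster_sizes = tuple(
                base + (1 if j < extra else 0) for j in range(self.k_true)
            )
        if sum(self.cluster_sizes) != self.n:
            raise ValueError("cluster sizes must sum to n")


def _axis_centers(k: int, d: int, separation: float) -> np.ndarray:
    """Cluster means: origin, then separation * ring * e_axis with the axis
    cycling through the relevant dimensions and the ring index growing.
    Any two centers are at least ``separation`` apart."""
    centers = np.zeros((k, d))
    for j in range(1, k):
        axis = (j - 1) % d
        ring = 1 + (j - 1) // d
        centers[j, axis] = separation * ring
    return centers


def _sample_cluster(shape: str, size: int, d: int, rng: np.random.Generator) -> np.ndarray:
    """Zero-centered cluster of unit within-cluster scale."""
    if shape == "spherical":
        return rng.normal(0.0, 1.0, size=(size, d))
    if shape == "elliptical":
        scales = np.array([ELLIPSE_AXES[i % len(ELLIPSE_AXES)] for i in range(d)])
        return rng.normal(0.0, 1.0, size=(size, d)) * scales
    # ring: uniform angle in the first two dims, Gaussian radial jitter;
    # remaining relevant dims get small Gaussian thickness
    angle = rng.uniform(0.0, 2.0 * np.pi, size=size)
    radius = RING_RADIUS + rng.normal(0.0, RING_JITTER_FRAC * RING_RADIUS, size=size)
    out = np.zeros((size, d))
    out[:, 0] = radius * np.cos(angle)
    out[:, 1] = radius * np.sin(angle)
    if d > 2:
        out[:, 2:] = rng.normal(0.0, RING_JITTER_FRAC * RING_RADIUS, size=(size, d - 2))
    return out


def generate_mixture(spec: SyntheticSpec) -> tuple[Dataset, np.ndarray]:
    """Generate a labeled table; returns (dataset, true_relevant_mask).

    Relevant columns come first, noise columns after; the mask marks the
    relevant ones.  Deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _axis_centers(spec.k_true, spec.relevant_d, spec.separation)

    blocks, labels = [], []
    for j, (shape, size) in enumerate(zip(spec.shapes, spec.cluster_sizes)):
        blocks.append(centers[j] + _sample_cluster(shape, size, spec.relevant_d, rng))
        labels.append(np.full(size, j, dtype=np.int64))
    relevant = np.vstack(blocks)
    true_labels = np.concatenate(labels)

    # shuffle sample order so labels are not block-sorted
    order = rng.permutation(spec.n)
    relevant, true_labels = relevant[order], true_labels[order]

    lo, hi = relevant.min(), relevant.max()
    noise = rng.uniform(lo, hi, size=(spec.n, spec.noise_d))
    points = np.hstack([relevant, noise])

    names = [f"x{i}" for i in range(spec.relevant_d)] + [
        f"noise{i}" for i in range(spec.noise_d)
    ]
    labeled_idx = label_subsample_labels(true_labels, spec.labeled_fraction, spec.seed)
    dataset = Dataset(
        points=points,
        feature_names=names,
        true_labels=true_labels,
        labeled_idx=labeled_idx,
    )
    mask = np.zeros(spec.relevant_d + spec.noise_d, dtype=bool)
    mask[: spec.relevant_d] = True
    return dataset, mask


def label_subsample_labels(true_labels: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Uniform labeled subset of size round(fraction*n), round-half-even."""
    return draw_labeled_idx(len(true_labels), fraction, seed)


def label_subsample(dataset: Dataset, fraction: float, seed: int) -> np.ndarray:
    """Draw a labeled index subset for an existing dataset with known labels."""
    if dataset.true_labels is None:
        raise ValueError("dataset has no true labels")
    return draw_labeled_idx(dataset.n, fraction, seed)
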