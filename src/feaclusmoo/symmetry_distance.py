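"""Point-symmetry distance.

The point-symmetry (PS) distance between a point ``x`` and a candidate
cluster center ``c`` asks how well the data supports ``x`` having a mirror
partner on the far side of ``c``.  The reflection of ``x`` through ``c`` is
``x* = 2c - x``; if real data points sit close to ``x*``, the cluster is
locally symmetric about ``c`` and the distance is small.  Concretely

    d_sym(x, c) = mean Euclidean distance from x* to its `knear`
                  coordinate-distinct nearest neighbours among all n points
    d_ps(x, c)  = d_sym(x, c) * d_e(x, c)

with ``d_e`` the plain Euclidean distance.  All quantities live in the
*active feature subspace*: points are first projected onto the currently
selected features.

The gate threshold θ is the maximum, over all points, of the distance to the
nearest other point ("nearest distinct index": a coincident duplicate counts
and contributes 0).  Assignment by symmetry is only trusted when
``d_sym < θ``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


class DegenerateSolutionError(ValueError):
    """A candidate solution cannot be scored (coincident centers, a cluster
    too small for the symmetry measure, an empty cluster, ...).  Callers in
    the search loop catch this and assign worst-case objective values."""


def reflected_point(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Reflection of ``x`` through ``c``: componentwise ``2c - x``."""
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    if x.shape != c.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {c.shape}")
    return 2.0 * c - x


def max_nn_distance(points: np.ndarray) -> float:
    """Symmetry threshold θ: max over points of the nearest-neighbour
    distance, where the neighbour is the nearest point with a *distinct
    index* (a coordinate-coincident duplicate yields distance 0)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = points.shape[0]
    if n < 2:
        raise ValueError("theta requires at least 2 points")
    tree = cKDTree(points)
    # k=2: the first hit is the point itself (distance 0, or a duplicate);
    # the second is the nearest other index.
    d, _ = tree.query(points, k=2)
    return float(np.max(d[:, 1]))


@dataclass
class DistanceContext:
    """Spatial context for PS-distance queries in one active subspace.

    Parameters
    ----------
    active_points : (n, d) array
        All n data points projected onto the active feature mask.
    knear : int
        Number of coordinate-distinct nearest neighbours of the reflected
        point that enter the symmetry measure (default 2).
    theta : float, optional
        Symmetry threshold; computed from ``active_points`` via
        :func:`max_nn_distance` when omitted.
    """

    active_points: np.ndarray
    knear: int = 2
    theta: float | None = None
    _tree: cKDTree = field(init=False, repr=False)
    _has_duplicates: bool = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.active_points, dtype=float))
        self.active_points = pts
        if self.knear < 1:
            raise ValueError("knear must be >= 1")
        n = pts.shape[0]
        if n < self.knear:
            raise ValueError(f"need at least knear={self.knear} points, got {n}")
        self._tree = cKDTree(pts)
        self._has_duplicates = len(np.unique(pts, axis=0)) < n
        if self.theta is None:
            self.theta = max_nn_distance(pts)
        elif self.theta < 0:
            raise ValueError("theta must be >= 0")

    # -- queries ---------------------------------------------------------

    def sym_measures(self, reflected: np.ndarray) -> np.ndarray:
        """d_sym for a batch of (virtual) reflected points: mean distance to
        the knear nearest coordinate-distinct data points."""
        reflected = np.atleast_2d(np.asarray(reflected, dtype=float))
        if not self._has_duplicates:
            d, _ = self._tree.query(reflected, k=self.knear)
            d = np.atleast_2d(d.reshape(reflected.shape[0], -1))
            return d.mean(axis=1)
        return _dedup_sym_measures(reflected, self.active_points, self.knear)


def _dedup_sym_measures(
    reflected: np.ndarray, points: np.ndarray, knear: int
) -> np.ndarray:
    """Exhaustive fallback when the data set contains coincident points:
    neighbours must have pairwise distinct coordinates."""
    uniq = np.unique(points, axis=0)
    if uniq.shape[0] < knear:
        raise DegenerateSolutionError(
            f"fewer than knear={knear} coordinate-distinct points available"
        )
    tree = cKDTree(uniq)
    d, _ = tree.query(reflected, k=knear)
    d = np.atleast_2d(d.reshape(reflected.shape[0], -1))
    return d.mean(axis=1)


def sym_measure(x: np.ndarray, c: np.ndarray, ctx: DistanceContext) -> float:
    """d_sym(x, c): mean distance from the reflection of ``x`` through ``c``
    to its knear coordinate-distinct nearest neighbours among all points."""
    return float(ctx.sym_measures(reflected_point(x, c)[None, :])[0])


def ps_distance(x: np.ndarray, c: np.ndarray, ctx: DistanceContext) -> float:
    """d_ps(x, c) = d_sym(x, c) * d_e(x, c) in the active subspace."""
    x = np.asarray(x, dtype=float)
    c = np.asarray(c, dtype=float)
    d_e = float(np.linalg.norm(x - c))
    if d_e == 0.0:
        return 0.0
    return sym_measure(x, c, ctx) * d_e
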