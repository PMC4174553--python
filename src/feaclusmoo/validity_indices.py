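"""Cluster validity measures.

Two internal indices score a partitioning without labels:

* **Sym-index** (maximise) — ratio of the largest inter-center distance to
  the total within-cluster point-symmetry distance, ``Sym = D_K / (K E_K)``.
  Large when clusters are far apart and each is symmetric about its own
  center.  The symmetry term searches reflected-point neighbours *within*
  the cluster: it measures the symmetry of a cluster about its center, not
  of the whole data set.
* **XB-index** (Xie–Beni, minimise) — within-cluster squared scatter over
  ``n`` times the squared minimum inter-center gap; small for compact,
  well-separated clusters.

Two external indices compare a candidate partition against a reference:

* **Adjusted Rand Index** (Hubert–Arabie) — chance-corrected pair agreement,
  1 for identical structure.
* **Minkowski score** — ``sqrt((n01 + n10) / (n11 + n10))`` over the pair
  counts; 0 is optimal.  Note the asymmetry: the reference partition T
  supplies the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .symmetry_distance import DegenerateSolutionError

__all__ = [
    "Partition",
    "PairCounts",
    "pair_counts",
    "minkowski_score",
    "adjusted_rand",
    "xb_index",
    "sym_index",
    "DegenerateSolutionError",
]


@dataclass(frozen=True)
class Partition:
    """Hard partition: integer labels in [0, K)."""

    labels: np.ndarray
    k: int

    @classmethod
    def from_labels(cls, labels) -> "Partition":
        """Relabel arbitrary hashable labels to 0..K-1 (order of first use)."""
        labels = np.asarray(labels)
        _, coded = np.unique(labels, return_inverse=True)
        return cls(labels=coded.astype(np.int64), k=int(coded.max()) + 1 if coded.size else 0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=np.int64))


@dataclass(frozen=True)
class PairCounts:
    """Pair-agreement counts between a reference T and candidate S.

    n11: same cluster in both; n01: same only in S; n10: same only in T;
    n00: different in both.  They sum to n(n-1)/2.
    """

    n11: int
    n01: int
    n10: int
    n00: int


def _labels(p) -> np.ndarray:
    return p.labels if isinstance(p, Partition) else np.asarray(p)


def _contingency(t: np.ndarray, s: np.ndarray) -> np.ndarray:
    ti = np.unique(t, return_inverse=True)[1]
    si = np.unique(s, return_inverse=True)[1]
    table = np.zeros((ti.max() + 1, si.max() + 1), dtype=np.int64)
    np.add.at(table, (ti, si), 1)
    return table


def pair_counts(T, S) -> PairCounts:
    """Count sample pairs by co-membership agreement, via the T×S
    contingency table (equivalent to enumerating all n(n-1)/2 pairs)."""
    t, s = _labels(T), _labels(S)
    if t.shape != s.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {s.shape}")
    n = t.size
    table = _contingency(t, s)

    def c2(x):
        return (x * (x - 1)) // 2

    n11 = int(c2(table).sum())
    same_t = int(c2(table.sum(axis=1)).sum())  # pairs co-clustered in T
    same_s = int(c2(table.sum(axis=0)).sum())  # pairs co-clustered in S
    n10 = same_t - n11
    n01 = same_s - n11
    total = n * (n - 1) // 2
    return PairCounts(n11=n11, n01=n01, n10=n10, n00=total - n11 - n01 - n10)


def minkowski_score(T, S) -> float:
    """sqrt((n01+n10)/(n11+n10)) with T the reference partition; 0 iff the
    two partitions induce the same pair structure."""
    pc = pair_counts(T, S)
    denom = pc.n11 + pc.n10
    if denom == 0:
        raise ValueError(
            "Minkowski score undefined: reference partition has no co-clustered pair"
        )
    return float(np.sqrt((pc.n01 + pc.n10) / denom))


def adjusted_rand(T, S) -> float:
    """Hubert–Arabie adjusted Rand index from the contingency table.

    The degenerate 0/0 case (both partitions a single cluster, or both
    all-singletons: perfect agreement with zero adjusted range) returns 1.
    """
    t, s = _labels(T), _labels(S)
    if t.shape != s.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {s.shape}")
    n = t.size
    if n < 2:
        raise ValueError("ARI requires n >= 2")
    table = _contingency(t, s)

    def c2(x):
        return (x * (x - 1)) / 2.0

    sum_ij = c2(table.astype(float)).sum()
    sum_a = c2(table.sum(axis=1).astype(float)).sum()
    sum_b = c2(table.sum(axis=0).astype(float)).sum()
    expected = sum_a * sum_b / c2(float(n))
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


# -- internal indices ----------------------------------------------------


def _project(data: np.ndarray, centers: np.ndarray, mask) -> tuple[np.ndarray, np.ndarray]:
    data = np.asarray(data, dtype=float)
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        data = data[:, mask]
        centers = centers[:, mask]
    return data, centers


def xb_index(data, partition, centers, mask=None) -> float:
    """Xie–Beni index in the active subspace.

    XB = sum_k sum_{x in C_k} ||x - c_k||^2 / (n * min_{i<j} ||c_i - c_j||^2)
    """
    x, c = _project(data, centers, mask)
    labels = _labels(partition)
    k = c.shape[0]
    if k < 2:
        raise DegenerateSolutionError("XB-index needs K >= 2")
    center_gaps = pdist(c)
    min_gap = center_gaps.min()
    if min_gap == 0.0:
        raise DegenerateSolutionError("coincident centers")
    scatter = float(np.sum((x - c[labels]) ** 2))
    return scatter / (x.shape[0] * float(min_gap) ** 2)


def sym_index(data, partition, centers, mask=None, knear: int = 2) -> float:
    """Sym-index: D_K / (K * E_K) in the active subspace.

    D_K is the largest inter-center distance; E_K sums, over every point,
    the point-symmetry distance to its cluster center with the reflected
    point's ``knear`` neighbours searched among that cluster's own members.
    A cluster with fewer than ``knear`` coordinate-distinct members (or an
    empty cluster, or E_K == 0) cannot be scored and raises
    :class:`DegenerateSolutionError`.
    """
    x, c = _project(data, centers, mask)
    labels = _labels(partition)
    k = c.shape[0]
    if k < 2:
        raise DegenerateSolutionError("Sym-index needs K >= 2")
    d_k = float(squareform(pdist(c)).max()) if k > 1 else 0.0

    e_k = 0.0
    for j in range(k):
        members = x[labels == j]
        if members.shape[0] == 0:
            raise DegenerateSolutionError(f"cluster {j} is empty")
        uniq = np.unique(members, axis=0)
        if uniq.shape[0] < knear:
            raise DegenerateSolutionError(
                f"cluster {j} has fewer than knear={knear} distinct members"
            )
        tree = cKDTree(uniq)
        reflected = 2.0 * c[j] - members
        d, _ = tree.query(reflected, k=knear)
        d_sym = np.atleast_2d(d.reshape(members.shape[0], -1)).mean(axis=1)
        d_e = np.linalg.norm(members - c[j], axis=1)
        e_k += float(np.sum(d_sym * d_e))
    if e_k == 0.0:
        raise DegenerateSolutionError("zero total symmetry distance")
    return d_k / (k * e_k)
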