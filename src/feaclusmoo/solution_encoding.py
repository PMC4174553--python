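"""Variable-length candidate encoding and mutation.

A candidate solution is the "string" the annealer searches over: a binary
feature mask of length F plus K cluster centers, each a full-length F
vector (encoded length F + K*F).  Only masked-in coordinates ever enter a
distance; inactive coordinates are carried and perturbed anyway, so a later
mask flip can reactivate a feature without losing center information.

Three mutation moves, chosen uniformly:

1. *perturb* — every center coordinate replaced by a Laplace draw centred on
   its old value with scale delta (default 1.0);
2. *delete*  — one uniformly chosen center removed (only if K > 2);
3. *insert*  — one uniformly chosen data point appended as a center (only if
   K < kmax).

Every move also flips each mask bit independently with probability
``flip_prob`` (default 1/F).  An infeasible delete/insert degrades to
perturb; an all-zero mask is redrawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tabular_io import Dataset


@dataclass(frozen=True)
class CandidateSolution:
    mask: np.ndarray     # (F,) uint8, at least one bit set
    centers: np.ndarray  # (K, F) float, full feature space

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=np.uint8))
        object.__setattr__(
            self, "centers", np.atleast_2d(np.asarray(self.centers, dtype=float))
        )
        if self.mask.sum() == 0:
            raise ValueError("feature mask must have at least one active bit")
        if self.centers.shape[1] != self.mask.shape[0]:
            raise ValueError("centers and mask disagree on feature count")
        if self.k < 2:
            raise ValueError("need at least 2 centers")

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    @property
    def n_features_active(self) -> int:
        return int(self.mask.sum())


@dataclass
class MutationParams:
    delta: float = 1.0        # Laplace scale of center perturbation
    flip_prob: float | None = None  # per-bit mask flip prob; None -> 1/F
    kmax: int = 10

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.flip_prob is not None and not 0.0 < self.flip_prob <= 1.0:
            raise ValueError("flip_prob must be in (0, 1]")
        if self.kmax < 2:
            raise ValueError("kmax must be >= 2")


def default_kmax(n: int) -> int:
    """Soft upper bound on the cluster count: round(sqrt(n)), at least 2."""
    return max(2, round(np.sqrt(n)))


def _random_mask(f: int, rng: np.random.Generator) -> np.ndarray:
    mask = rng.integers(0, 2, size=f, dtype=np.uint8)
    while mask.sum() == 0:
        mask = rng.integers(0, 2, size=f, dtype=np.uint8)
    return mask


def random_solution(dataset: Dataset, kmax: int, rng: np.random.Generator) -> CandidateSolution:
    """Fresh string: K = 2 + (rand mod (kmax-1)) centers sampled as distinct
    data points, mask bits i.i.d. uniform (redrawn if all zero)."""
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    if kmax > dataset.n:
        raise ValueError(f"kmax={kmax} exceeds sample count n={dataset.n}")
    k = 2 + int(rng.integers(0, np.iinfo(np.int64).max)) % (kmax - 1) if kmax > 2 else 2
    idx = rng.choice(dataset.n, size=k, replace=False)
    return CandidateSolution(
        mask=_random_mask(dataset.n_features, rng),
        centers=dataset.points[idx].copy(),
    )


def mutate(
    sol: CandidateSolution,
    dataset: Dataset,
    params: MutationParams,
    rng: np.random.Generator,
    freeze_mask: bool = False,
) -> CandidateSolution:
    """One mutation step; returns a new solution, input untouched.

    ``freeze_mask=True`` (used by the no-feature-selection variant) keeps
    the mask fixed and applies only the center moves.
    """
    move = ("perturb", "delete", "insert")[rng.integers(0, 3)]
    if move == "delete" and sol.k <= 2:
        move = "perturb"
    if move == "insert" and sol.k >= params.kmax:
        move = "perturb"

    if move == "perturb":
        centers = rng.laplace(loc=sol.centers, scale=params.delta)
    elif move == "delete":
        drop = int(rng.integers(0, sol.k))
        centers = np.delete(sol.centers, drop, axis=0)
    else:  # insert
        pick = int(rng.integers(0, dataset.n))
        centers = np.vstack([sol.centers, dataset.points[pick]])

    if freeze_mask:
        mask = sol.mask.copy()
    else:
        f = sol.mask.shape[0]
        flip_prob = params.flip_prob if params.flip_prob is not None else 1.0 / f
        flips = rng.random(f) < flip_prob
        mask = np.where(flips, 1 - sol.mask, sol.mask).astype(np.uint8)
        if mask.sum() == 0:
            mask = _random_mask(f, rng)
    return CandidateSolution(mask=mask, centers=centers)
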