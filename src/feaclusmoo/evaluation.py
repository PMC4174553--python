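"""Comparison protocol: dense ranks, average ranks, Friedman and Nemenyi.

Algorithms are compared across datasets on their Minkowski scores.  Within
each dataset row the scores receive *dense* ranks (the smallest score gets
rank 1, ties share the rank of their distinct value, the next distinct
value gets the next integer); columns are then averaged.  The Friedman test
asks whether the algorithms' rank profiles could have arisen under
exchangeability; it is computed from within-row *average*-style
(mid-rank, tie-corrected) ranks, the form the chi-square reference
distribution assumes — dense ranks do not sum to A(A+1)/2 per row, so both
rank styles are exposed but only mid-ranks feed the statistic.  Nemenyi's
critical difference then bounds which pairwise average-rank gaps are
significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, rankdata

#: Best-of-ten Minkowski scores of six clustering algorithms on seven UCI
#: tables, as published in the benchmark comparison this protocol mirrors.
#: Rows: datasets; columns: algorithms (lower is better).
BENCHMARK_ALGORITHMS = (
    "Semi-FeaClusMOO",
    "Semi-FeaClusMOO-Euc",
    "FeaClusMOO",
    "VAMOSA",
    "VGAPS",
    "KMeans",
)
BENCHMARK_DATASETS = (
    "Iris", "Cancer", "Newthyroid", "Wine", "LiverDisorder", "LungCancer", "Glass",
)
BENCHMARK_SCORES = np.array(
    [
        [0.39, 0.39, 0.44, 0.80, 0.62, 0.68],
        [0.31, 0.37, 0.31, 0.32, 0.37, 0.37],
        [0.46, 0.47, 0.54, 0.57, 0.58, 0.94],
        [0.62, 0.64, 0.67, 0.97, 1.12, 1.40],
        [0.64, 0.98, 0.98, 0.98, 0.98, 0.98],
        [0.70, 0.71, 0.70, 0.85, 1.24, 1.45],
        [1.03, 1.05, 1.05, 1.08, 1.10, 1.69],
    ]
)


def dense_ranks(row) -> np.ndarray:
    """Dense rank of each score: 1 + number of distinct smaller values."""
    row = np.asarray(row, dtype=float)
    if not np.all(np.isfinite(row)):
        raise ValueError("scores must be finite")
    return rankdata(row, method="dense").astype(int)


@dataclass
class RankTable:
    """Scores (D datasets x A algorithms), their dense ranks, and averages."""

    scores: np.ndarray
    algorithms: tuple[str, ...] | None = None
    datasets: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        d, a = self.scores.shape
        if self.algorithms is None:
            self.algorithms = tuple(f"alg{i}" for i in range(a))
        if self.datasets is None:
            self.datasets = tuple(f"dataset{i}" for i in range(d))
        self.ranks = np.vstack([dense_ranks(r) for r in self.scores])

    @property
    def avg_ranks(self) -> np.ndarray:
        return self.ranks.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ranks, index=list(self.datasets), columns=list(self.algorithms))


def average_ranks(table: RankTable) -> np.ndarray:
    """Column means of the dense-rank matrix."""
    return table.avg_ranks


def friedman_test(scores) -> tuple[float, float]:
    """Tie-corrected Friedman chi-square over a D x A score matrix.

    Mid-ranks are recomputed from the scores within each row.  Statistic:
    chi2 = [12 / (D A (A+1))] * sum_j Rj^2 - 3 D (A+1), divided by the tie
    correction 1 - sum(t^3 - t) / (D A (A^2 - 1)); p-value from chi-square
    with A-1 degrees of freedom.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    d, a = scores.shape
    if d < 2 or a < 2:
        raise ValueError("need at least 2 datasets and 2 algorithms")
    ranks = np.vstack([rankdata(r, method="average") for r in scores])
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (d * a * (a + 1)) * np.sum(col_sums**2) - 3.0 * d * (a + 1)

    tie_term = 0.0
    for row in scores:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (d * a * (a**2 - 1))
    if correction <= 0.0:
        raise ValueError("degenerate score table: all scores tied within rows")
    stat /= correction
    return float(stat), float(chi2.sf(stat, a - 1))


#: q_alpha constants for the Nemenyi test (infinite-df studentized range
#: divided by sqrt(2)), indexed by number of algorithms A = 2..10.
_NEMENYI_Q = {
    0.05: {2: 1.960, 3: 2.343, 4: 2.569, 5: 2.728, 6: 2.850, 7: 2.949, 8: 3.031, 9: 3.102, 10: 3.164},
    0.10: {2: 1.645, 3: 2.052, 4: 2.291, 5: 2.459, 6: 2.589, 7: 2.693, 8: 2.780, 9: 2.855, 10: 2.920},
}


def nemenyi_critical_difference(n_algorithms: int, n_datasets: int, alpha: float = 0.05) -> float:
    """CD = q_alpha(A) * sqrt(A (A+1) / (6 D)); two average ranks further
    apart than CD differ significantly at level alpha."""
    if alpha not in _NEMENYI_Q:
        raise ValueError(f"alpha must be one of {sorted(_NEMENYI_Q)}, got {alpha}")
    if n_algorithms not in _NEMENYI_Q[alpha]:
        raise ValueError(f"supported algorithm counts are 2..10, got {n_algorithms}")
    if n_datasets < 1:
        raise ValueError("need at least one dataset")
    q = _NEMENYI_Q[alpha][n_algorithms]
    return q * float(np.sqrt(n_algorithms * (n_algorithms + 1) / (6.0 * n_datasets)))


def benchmark_rank_table() -> RankTable:
    """The published six-algorithm benchmark as a ready-made rank table."""
    return RankTable(
        scores=BENCHMARK_SCORES,
        algorithms=BENCHMARK_ALGORITHMS,
        datasets=BENCHMARK_DATASETS,
    )
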