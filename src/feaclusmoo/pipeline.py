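"""Semi-supervised feature-selecting clustering pipeline.

Wires the candidate encoding, the point-symmetry distance and the validity
indices into the AMOSA annealer, for five variants:

========== ============== ==================================== ==========
name       assignment     objectives (direction)               mask
========== ============== ==================================== ==========
semi-ps    point-symmetry Sym (max), XB (min), ARI (max),      searched
                          feature count (max)
semi-euc   Euclidean      same four                            searched
feaclus    point-symmetry Sym (max), XB (min), feat count (max) searched
vamosa     point-symmetry Sym (max), XB (min)                  all ones
kmeans     Euclidean      within-cluster sum of squares        all ones
========== ============== ==================================== ==========

Assignment under the point-symmetry distance: each point goes to the center
minimising d_ps, *provided* the corresponding d_sym is below the threshold
θ (no trustworthy mirror partner -> fall back to the nearest Euclidean
center).  The ARI objective compares the induced partition with the true
classes on the labeled subset only; it is how the 10% supervision steers
the search.  Degenerate candidates (coincident centers, empty or too-small
clusters) are not discarded but scored with a worst-case objective vector
so the annealer can move through them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from . import solution_encoding as enc
from . import validity_indices as vi
from .amosa_core import AmosaConfig, Archive, ObjectiveSpec, anneal
from .symmetry_distance import DegenerateSolutionError, DistanceContext, max_nn_distance
from .tabular_io import Dataset, RunResult

XB_WORST = 1e12  # worst-case XB for degenerate candidates
WORST_OBJECTIVES = {"sym": 0.0, "xb": XB_WORST, "ari": -1.0, "nfeat": 0.0}

OBJECTIVE_DIRECTIONS = {"sym": "max", "xb": "min", "ari": "max", "nfeat": "max"}


@dataclass(frozen=True)
class VariantSpec:
    name: str
    distance: str                 # "point-symmetry" | "euclidean"
    objectives: tuple[str, ...]   # ordered subset of sym/xb/ari/nfeat
    feature_selection: bool

    def objective_spec(self) -> ObjectiveSpec:
        return ObjectiveSpec(tuple(OBJECTIVE_DIRECTIONS[o] for o in self.objectives))

    @property
    def semi_supervised(self) -> bool:
        return "ari" in self.objectives


VARIANTS: dict[str, VariantSpec] = {
    "semi-ps": VariantSpec("semi-ps", "point-symmetry", ("sym", "xb", "ari", "nfeat"), True),
    "semi-euc": VariantSpec("semi-euc", "euclidean", ("sym", "xb", "ari", "nfeat"), True),
    "feaclus": VariantSpec("feaclus", "point-symmetry", ("sym", "xb", "nfeat"), True),
    "vamosa": VariantSpec("vamosa", "point-symmetry", ("sym", "xb"), False),
}


# -- assignment ----------------------------------------------------------


def assign_points(
    dataset: Dataset,
    sol: enc.CandidateSolution,
    distance: str = "point-symmetry",
    knear: int = 2,
    theta: float | None = None,
    theta_scope: str = "subspace",
) -> np.ndarray:
    """Partition labels induced by a candidate's centers and mask.

    Point-symmetry mode: k* = argmin_k d_ps(x, c_k), kept when
    d_sym(x, c_k*) < θ, else the Euclidean-nearest center.  ``theta`` may be
    forced (0 -> pure Euclidean, inf -> pure argmin-d_ps); by default it is
    the max nearest-neighbour distance in the active subspace
    (``theta_scope="subspace"``) or over all features ("full").
    """
    mask = sol.mask.astype(bool)
    x = dataset.points[:, mask]
    c = sol.centers[:, mask]
    if c.shape[0] > 1 and cdist(c, c)[np.triu_indices(c.shape[0], 1)].min() == 0.0:
        raise DegenerateSolutionError("coincident centers in active subspace")

    d_e = cdist(x, c)
    if distance == "euclidean":
        return d_e.argmin(axis=1)
    if distance != "point-symmetry":
        raise ValueError(f"unknown distance {distance!r}")

    if theta is None:
        theta = (
            max_nn_distance(x)
            if theta_scope == "subspace"
            else max_nn_distance(dataset.points)
        )
    ctx = DistanceContext(active_points=x, knear=knear, theta=theta)
    d_sym = np.column_stack(
        [ctx.sym_measures(2.0 * c[k] - x) for k in range(c.shape[0])]
    )
    d_ps = d_sym * d_e
    k_star = d_ps.argmin(axis=1)
    gate = d_sym[np.arange(x.shape[0]), k_star] < theta
    return np.where(gate, k_star, d_e.argmin(axis=1))


# -- objective evaluation ------------------------------------------------


def evaluate_objectives(
    dataset: Dataset,
    sol: enc.CandidateSolution,
    variant: VariantSpec,
    knear: int = 2,
    theta_scope: str = "subspace",
) -> np.ndarray:
    """Objective vector for one candidate under one variant.

    Degenerate candidates receive the worst-case vector instead of raising.
    """
    try:
        labels = assign_points(
            dataset, sol, variant.distance, knear=knear, theta_scope=theta_scope
        )
        values = {}
        mask = sol.mask.astype(bool)
        for name in variant.objectives:
            if name == "sym":
                values["sym"] = vi.sym_index(
                    dataset.points, labels, sol.centers, mask, knear=knear
                )
            elif name == "xb":
                # every encoded center is its own cluster: empty ones degenerate
                if len(np.unique(labels)) < sol.k:
                    raise DegenerateSolutionError("empty cluster")
                values["xb"] = vi.xb_index(dataset.points, labels, sol.centers, mask)
            elif name == "ari":
                idx = dataset.labeled_idx
                values["ari"] = vi.adjusted_rand(
                    dataset.true_labels[idx], labels[idx]
                )
            elif name == "nfeat":
                values["nfeat"] = float(sol.n_features_active)
    except DegenerateSolutionError:
        return np.array([WORST_OBJECTIVES[o] for o in variant.objectives])
    return np.array([values[o] for o in variant.objectives])


# -- problem adapter -----------------------------------------------------


@dataclass
class ClusteringProblem:
    """Adapter giving AMOSA its random_solution/mutate/evaluate surface.

    With ``center_update`` (the default) every fresh or mutated string is
    refined by one K-means-style step before it enters the search: points
    are assigned with the variant's distance and each center is replaced by
    the mean of its cluster (empty clusters keep their center).  This
    Lamarckian refinement keeps archive members' centers consistent with
    the partitions they induce; without it the archive accumulates
    solutions whose labeled-point scores are perfect but whose centers are
    arbitrary, and short annealing schedules fail to converge.
    """

    dataset: Dataset
    variant: VariantSpec
    kmax: int
    mutation: enc.MutationParams = field(default=None)
    knear: int = 2
    theta_scope: str = "subspace"
    center_update: bool = True

    def __post_init__(self) -> None:
        if self.mutation is None:
            self.mutation = enc.MutationParams(kmax=self.kmax)
        self.objective_spec = self.variant.objective_spec()

    def refine_centers(self, sol: enc.CandidateSolution) -> enc.CandidateSolution:
        """One assignment + mean-update step (identity for degenerate
        strings, which evaluation scores worst-case anyway)."""
        try:
            labels = assign_points(
                self.dataset, sol, self.variant.distance,
                knear=self.knear, theta_scope=self.theta_scope,
            )
        except DegenerateSolutionError:
            return sol
        centers = sol.centers.copy()
        for k in range(sol.k):
            members = self.dataset.points[labels == k]
            if len(members):
                centers[k] = members.mean(axis=0)
        return enc.CandidateSolution(mask=sol.mask.copy(), centers=centers)

    def random_solution(self, rng) -> enc.CandidateSolution:
        sol = enc.random_solution(self.dataset, self.kmax, rng)
        if not self.variant.feature_selection:
            sol = enc.CandidateSolution(
                mask=np.ones(self.dataset.n_features, dtype=np.uint8),
                centers=sol.centers,
            )
        return self.refine_centers(sol) if self.center_update else sol

    def mutate(self, sol, rng) -> enc.CandidateSolution:
        out = enc.mutate(
            sol,
            self.dataset,
            self.mutation,
            rng,
            freeze_mask=not self.variant.feature_selection,
        )
        return self.refine_centers(out) if self.center_update else out

    def evaluate(self, sol) -> np.ndarray:
        return evaluate_objectives(
            self.dataset, sol, self.variant, knear=self.knear, theta_scope=self.theta_scope
        )


# -- best-solution selection ---------------------------------------------


def select_best_solution(
    archive: Archive, dataset: Dataset, sym_position: int | None = None
) -> int:
    """Pick the archive member whose nearest-Euclidean-center assignment of
    the labeled points best matches their true classes (minimum Minkowski
    score).

    With few labeled points the score saturates at 0 for several members;
    exact ties are therefore broken by the largest Sym-index objective when
    ``sym_position`` locates one in the members' objective vectors (archive
    order is search history, not a meaningful preference), and finally by
    lower index.
    """
    if not archive.members:
        raise ValueError("empty archive")
    if dataset.labeled_idx.size == 0:
        raise ValueError("no labeled points available for selection")
    idx = dataset.labeled_idx
    truth = dataset.true_labels[idx]
    best, best_key = 0, None
    for i, (sol, obj) in enumerate(archive.members):
        mask = sol.mask.astype(bool)
        assigned = cdist(dataset.points[idx][:, mask], sol.centers[:, mask]).argmin(axis=1)
        score = vi.minkowski_score(truth, assigned)
        key = (score, -obj[sym_position]) if sym_position is not None else (score,)
        if best_key is None or key < best_key:
            best, best_key = i, key
    return best


def select_max_sym(archive: Archive, sym_position: int = 0) -> int:
    """Unsupervised fallback: archive member with the largest Sym-index."""
    if not archive.members:
        raise ValueError("empty archive")
    values = [obj[sym_position] for _, obj in archive.members]
    return int(np.argmax(values))


# -- run drivers ---------------------------------------------------------


def _result_from_archive(
    archive: Archive,
    best: int,
    dataset: Dataset,
    variant: VariantSpec,
    metadata: dict,
    knear: int = 2,
    theta_scope: str = "subspace",
) -> RunResult:
    solutions = [
        {
            "mask": "".join(map(str, sol.mask.tolist())),
            "centers": sol.centers.tolist(),
            "objectives": obj.tolist(),
        }
        for sol, obj in archive.members
    ]
    best_sol = archive.members[best][0]
    partition = assign_points(
        dataset, best_sol, variant.distance, knear=knear, theta_scope=theta_scope
    )
    return RunResult(
        archive_solutions=solutions,
        best_solution=best,
        partition=partition,
        metadata=metadata,
    )


def run_variant(
    dataset: Dataset,
    variant: VariantSpec | str,
    config: AmosaConfig | None = None,
    kmax: int | None = None,
    rng: np.random.Generator | int = 0,
    knear: int = 2,
    theta_scope: str = "subspace",
    selection: str | None = None,
    center_update: bool = True,
) -> RunResult:
    """Full annealing run for one variant; returns the selected solution's
    partition plus the whole archive.

    Semi-supervised variants select the final solution by minimum Minkowski
    score over the labeled points; unsupervised variants by maximum
    Sym-index (override with ``selection``).
    """
    if isinstance(variant, str):
        variant = VARIANTS[variant]
    if config is None:
        config = AmosaConfig()
    if kmax is None:
        kmax = enc.default_kmax(dataset.n)
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = None
    if variant.semi_supervised and dataset.labeled_idx.size == 0:
        raise ValueError(f"variant {variant.name!r} requires labeled points")

    problem = ClusteringProblem(
        dataset=dataset, variant=variant, kmax=kmax, knear=knear,
        theta_scope=theta_scope, center_update=center_update,
    )
    archive = anneal(problem, config, rng)

    if selection is None:
        selection = "minkowski" if variant.semi_supervised else "max-sym"
    if selection == "minkowski":
        sym_position = (
            variant.objectives.index("sym") if "sym" in variant.objectives else None
        )
        best = select_best_solution(archive, dataset, sym_position=sym_position)
    elif selection == "max-sym":
        best = select_max_sym(archive, sym_position=variant.objectives.index("sym"))
    else:
        raise ValueError(f"unknown selection rule {selection!r}")

    metadata = {
        "variant": variant.name,
        "seed": seed,
        "kmax": kmax,
        "selection": selection,
        "config": {
            "soft_limit": config.soft_limit,
            "hard_limit": config.hard_limit,
            "iter_per_temp": config.iter_per_temp,
            "t_max": config.t_max,
            "t_min": config.t_min,
            "alpha": config.alpha,
            "gamma": config.gamma,
        },
    }
    return _result_from_archive(
        archive, best, dataset, variant, metadata, knear=knear, theta_scope=theta_scope
    )


def kmeans_baseline(dataset: Dataset, k: int, rng: np.random.Generator | int = 0) -> RunResult:
    """K-means with all features: Lloyd iterations from random data-point
    seeds, best of 10 restarts by within-cluster sum of squares."""
    if not 2 <= k <= dataset.n:
        raise ValueError(f"k must be in [2, n], got {k}")
    if isinstance(rng, (int, np.integer)):
        seed = int(rng)
    else:
        seed = int(rng.integers(0, 2**31 - 1))
    km = KMeans(
        n_clusters=k, init="random", n_init=10, max_iter=300, tol=0.0,
        random_state=seed,
    ).fit(dataset.points)
    solutions = [
        {
            "mask": "1" * dataset.n_features,
            "centers": km.cluster_centers_.tolist(),
            "objectives": [float(km.inertia_)],
        }
    ]
    return RunResult(
        archive_solutions=solutions,
        best_solution=0,
        partition=km.labels_.astype(np.int64),
        metadata={"variant": "kmeans", "seed": seed, "k": k, "wcss": float(km.inertia_)},
    )
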