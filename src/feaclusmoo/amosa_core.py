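"""Archived multiobjective simulated annealing (AMOSA).

A simulated-annealing search over an abstract problem that maintains an
*archive* of mutually non-dominated solutions.  The archive has a soft size
limit SL and a hard limit HL (SL > HL); whenever it outgrows SL it is
compressed to HL by single-linkage clustering in objective space, keeping
one representative per cluster.

Acceptance is governed by Pareto-domination status and by the *amount of
domination*: the product, over objectives on which two solutions differ, of
the range-normalised objective gap.  A dominated proposal is still accepted
as the current point with probability

    p = 1 / (1 + exp(dom_avg / T))

where dom_avg averages the amount of domination over the solutions that
dominate it — a logistic gate that opens at high temperature and closes as
T -> 0.  The three-way decision table (proposal dominated / incomparable /
dominating, each crossed with its archive status) is implemented in
:meth:`Amosa._step`; the probability itself is isolated in
:func:`acceptance_probability` so alternative forms can be swapped in.

The problem interface is duck-typed: ``random_solution(rng)``,
``mutate(solution, rng)``, ``evaluate(solution) -> objective vector``, and
an :class:`ObjectiveSpec` giving per-objective directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

RANGE_FLOOR = 1e-12  # per-objective range floor avoids division by zero


@dataclass(frozen=True)
class AmosaConfig:
    """Annealing schedule and archive limits.

    Defaults follow the published setting: SL=100, HL=50, 50 iterations per
    temperature, Tmax=100, Tmin=1e-5, cooling rate 0.9; gamma scales the
    initial solution pool (gamma*SL random starts, each hill-climbed).
    """

    soft_limit: int = 100
    hard_limit: int = 50
    iter_per_temp: int = 50
    t_max: float = 100.0
    t_min: float = 0.00001
    alpha: float = 0.9
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if not self.soft_limit > self.hard_limit >= 1:
            raise ValueError("require SL > HL >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("cooling rate must be in (0, 1)")
        if not self.t_max > self.t_min > 0.0:
            raise ValueError("require t_max > t_min > 0")
        if self.gamma <= 1.0:
            raise ValueError("gamma must be > 1")

    def n_temperature_levels(self) -> int:
        """Number of temperatures visited: T = t_max * alpha^t while T >= t_min."""
        return 1 + math.floor(math.log(self.t_min / self.t_max) / math.log(self.alpha))


@dataclass(frozen=True)
class ObjectiveSpec:
    """Per-objective optimisation directions ('max' or 'min')."""

    directions: tuple[str, ...]

    def __post_init__(self) -> None:
        for d in self.directions:
            if d not in ("max", "min"):
                raise ValueError(f"direction must be 'max' or 'min', got {d!r}")

    @property
    def n_objectives(self) -> int:
        return len(self.directions)

    def signs(self) -> np.ndarray:
        """+1 for maximised objectives, -1 for minimised (so that larger
        signed value is always better)."""
        return np.array([1.0 if d == "max" else -1.0 for d in self.directions])


def dominates(u, v, spec: ObjectiveSpec) -> bool:
    """Pareto dominance: u no worse than v everywhere (per direction) and
    strictly better somewhere."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.shape != (spec.n_objectives,):
        raise ValueError("objective vector length mismatch")
    s = spec.signs()
    su, sv = s * u, s * v
    return bool(np.all(su >= sv) and np.any(su > sv))


def amount_of_domination(u, v, ranges) -> float:
    """Product over differing objectives of |u_i - v_i| / R_i; 0 when u == v
    (empty-product convention)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    ranges = np.asarray(ranges, dtype=float)
    if np.any(ranges <= 0):
        raise ValueError("objective ranges must be positive")
    diff = np.abs(u - v)
    active = diff > 0
    if not active.any():
        return 0.0
    return float(np.prod(diff[active] / ranges[active]))


def acceptance_probability(dom_avg: float, temperature: float) -> float:
    """Probability of accepting a dominated proposal: logistic in
    -dom_avg/T.  Monotone increasing in T, decreasing in dom_avg."""
    z = dom_avg / temperature
    if z > 700.0:  # exp overflow guard; p is 0 to double precision anyway
        return 0.0
    return 1.0 / (1.0 + math.exp(z))


def nondominated_filter(points, spec: ObjectiveSpec) -> list[int]:
    """Indices of vectors not dominated by any other (brute-force-equivalent)."""
    pts = [np.asarray(p, dtype=float) for p in points]
    keep = []
    for i, u in enumerate(pts):
        if not any(dominates(v, u, spec) for j, v in enumerate(pts) if j != i):
            keep.append(i)
    return keep


@dataclass
class Archive:
    """Bounded set of mutually non-dominated (solution, objectives) pairs."""

    spec: ObjectiveSpec
    soft_limit: int
    hard_limit: int
    members: list[tuple[object, np.ndarray]] = field(default_factory=list)

    def objective_matrix(self) -> np.ndarray:
        return np.array([obj for _, obj in self.members], dtype=float)

    def try_add(self, solution, objectives) -> bool:
        """Insert if non-dominated w.r.t. the archive, purging any members
        the newcomer dominates.  Returns True if inserted."""
        objectives = np.asarray(objectives, dtype=float)
        if any(dominates(obj, objectives, self.spec) for _, obj in self.members):
            return False
        self.members = [
            m for m in self.members if not dominates(objectives, m[1], self.spec)
        ]
        self.members.append((solution, objectives))
        return True

    def dominating_members(self, objectives) -> list[int]:
        return [
            i for i, (_, obj) in enumerate(self.members)
            if dominates(obj, objectives, self.spec)
        ]


def reduce_archive(archive: Archive, target: int) -> Archive:
    """Compress the archive to ``target`` members by single-linkage
    clustering of the objective vectors (min-max normalised per objective,
    minimised objectives sign-flipped) and keeping, per cluster, the member
    nearest the cluster's objective-space centroid (ties -> lower index)."""
    if target < 1:
        raise ValueError("target must be >= 1")
    m = len(archive.members)
    if m <= target:
        return archive
    obj = archive.objective_matrix() * archive.spec.signs()
    lo, hi = obj.min(axis=0), obj.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    norm = (obj - lo) / span

    labels = fcluster(linkage(pdist(norm), method="single"), t=target, criterion="maxclust")
    keep: list[int] = []
    for cl in np.unique(labels):
        idx = np.flatnonzero(labels == cl)
        centroid = norm[idx].mean(axis=0)
        dist = np.linalg.norm(norm[idx] - centroid, axis=1)
        keep.append(int(idx[np.argmin(dist)]))  # argmin ties -> lower index
    keep.sort()
    archive.members = [archive.members[i] for i in keep]
    return archive


class Amosa:
    """One annealing run over a problem instance."""

    def __init__(self, problem, config: AmosaConfig, rng: np.random.Generator):
        self.problem = problem
        self.config = config
        self.rng = rng
        self.spec: ObjectiveSpec = problem.objective_spec
        self.archive = Archive(
            spec=self.spec,
            soft_limit=config.soft_limit,
            hard_limit=config.hard_limit,
        )
        self.n_evaluations = 0

    # -- helpers ---------------------------------------------------------

    def _evaluate(self, solution) -> np.ndarray:
        self.n_evaluations += 1
        return np.asarray(self.problem.evaluate(solution), dtype=float)

    def _ranges(self, *extra: np.ndarray) -> np.ndarray:
        """Per-objective ranges over archive plus the given vectors."""
        stack = [obj for _, obj in self.archive.members] + list(extra)
        mat = np.array(stack, dtype=float)
        r = mat.max(axis=0) - mat.min(axis=0)
        return np.maximum(r, RANGE_FLOOR)

    def _enforce_soft_limit(self) -> None:
        if len(self.archive.members) > self.config.soft_limit:
            reduce_archive(self.archive, self.config.hard_limit)

    # -- phases ----------------------------------------------------------

    def _initialize(self) -> None:
        n_init = int(round(self.config.gamma * self.config.soft_limit))
        pool = []
        for _ in range(n_init):
            sol = self.problem.random_solution(self.rng)
            obj = self._evaluate(sol)
            # hill-climb: accept a mutant only if it dominates
            for _ in range(self.config.iter_per_temp):
                cand = self.problem.mutate(sol, self.rng)
                cobj = self._evaluate(cand)
                if dominates(cobj, obj, self.spec):
                    sol, obj = cand, cobj
            pool.append((sol, obj))
        for i in nondominated_filter([obj for _, obj in pool], self.spec):
            self.archive.try_add(*pool[i])
        if len(self.archive.members) > self.config.hard_limit:
            reduce_archive(self.archive, self.config.hard_limit)

    def _step(self, current, current_obj, temperature: float):
        """One proposal/acceptance step; returns the new (current, obj)."""
        new = self.problem.mutate(current, self.rng)
        new_obj = self._evaluate(new)
        ranges = self._ranges(current_obj, new_obj)
        arch_dom = self.archive.dominating_members(new_obj)  # members dominating new

        if dominates(current_obj, new_obj, self.spec):
            # Case A: proposal dominated by current (and possibly archive)
            doms = [amount_of_domination(current_obj, new_obj, ranges)]
            doms += [
                amount_of_domination(self.archive.members[i][1], new_obj, ranges)
                for i in arch_dom
            ]
            p = acceptance_probability(float(np.mean(doms)), temperature)
            if self.rng.random() < p:
                return new, new_obj
            return current, current_obj

        if dominates(new_obj, current_obj, self.spec):
            # Case C: proposal dominates current
            if arch_dom:
                # archive still dominates the proposal: with prob 1/2 jump to
                # the dominating member closest in amount of domination
                if self.rng.random() < 0.5:
                    doms = [
                        amount_of_domination(self.archive.members[i][1], new_obj, ranges)
                        for i in arch_dom
                    ]
                    pick = arch_dom[int(np.argmin(doms))]
                    sol, obj = self.archive.members[pick]
                    return sol, obj.copy()
                return new, new_obj
            self.archive.try_add(new, new_obj)
            self._enforce_soft_limit()
            return new, new_obj

        # Case B: current and proposal incomparable -> arbitrate via archive
        if arch_dom:
            doms = [
                amount_of_domination(self.archive.members[i][1], new_obj, ranges)
                for i in arch_dom
            ]
            p = acceptance_probability(float(np.mean(doms)), temperature)
            if self.rng.random() < p:
                return new, new_obj
            return current, current_obj
        self.archive.try_add(new, new_obj)
        self._enforce_soft_limit()
        return new, new_obj

    def run(self) -> Archive:
        self._initialize()
        pick = int(self.rng.integers(0, len(self.archive.members)))
        current, current_obj = self.archive.members[pick]
        current_obj = current_obj.copy()

        temperature = self.config.t_max
        while temperature >= self.config.t_min:
            for _ in range(self.config.iter_per_temp):
                current, current_obj = self._step(current, current_obj, temperature)
            temperature *= self.config.alpha
        return self.archive


def anneal(problem, config: AmosaConfig, rng: np.random.Generator) -> Archive:
    """Run AMOSA on ``problem``; returns the final archive."""
    return Amosa(problem, config, rng).run()
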