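"""Archive, domination, and annealing behaviour of the AMOSA core."""

import numpy as np
import pytest

from feaclusmoo.amosa_core import (
    AmosaConfig,
    Archive,
    ObjectiveSpec,
    acceptance_probability,
    amount_of_domination,
    anneal,
    dominates,
    nondominated_filter,
    reduce_archive,
)

MAX2 = ObjectiveSpec(("max", "max"))


def brute_nondominated(points, spec):
    """O(m^2) oracle."""
    keep = []
    for i, u in enumerate(points):
        if not any(dominates(v, u, spec) for j, v in enumerate(points) if j != i):
            keep.append(i)
    return keep


class TestDominates:
    def test_strictly_better_everywhere(self):
        assert dominates((2, 2), (1, 1), MAX2)

    def test_incomparable_both_ways(self):
        assert not dominates((2, 1), (1, 2), MAX2)
        assert not dominates((1, 2), (2, 1), MAX2)

    def test_equal_vectors_do_not_dominate(self):
        assert not dominates((1, 1), (1, 1), MAX2)

    def test_directions_respected(self):
        spec = ObjectiveSpec(("max", "min"))
        assert dominates((2, 1), (1, 2), spec)
        assert not dominates((1, 2), (2, 1), spec)


class TestAmountOfDomination:
    def test_normalized_product(self):
        assert amount_of_domination((2, 4), (1, 2), (2, 4)) == pytest.approx(0.25)

    def test_equal_vectors_give_zero(self):
        assert amount_of_domination((3, 3), (3, 3), (1, 1)) == 0.0

    def test_full_range_single_gap(self):
        assert amount_of_domination((0, 5), (0, 1), (1, 4)) == pytest.approx(1.0)

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError):
            amount_of_domination((1, 2), (0, 0), (0, 1))


class TestAcceptanceProbability:
    def test_monotone_in_temperature_and_domination(self):
        assert acceptance_probability(0.5, 10.0) > acceptance_probability(0.5, 0.1)
        assert acceptance_probability(0.1, 1.0) > acceptance_probability(0.9, 1.0)

    def test_limits(self):
        assert acceptance_probability(0.5, 1e-12) == 0.0
        assert acceptance_probability(0.5, 1e12) == pytest.approx(0.5, abs=1e-6)
        assert acceptance_probability(1.0, 1.0) < 0.5


class TestNondominatedFilter:
    def test_small_example(self):
        pts = [(1, 3), (3, 1), (2, 2), (1, 1)]
        assert nondominated_filter(pts, MAX2) == [0, 1, 2]

    def test_identical_vectors_all_kept(self):
        pts = [(2, 2)] * 4
        assert nondominated_filter(pts, MAX2) == [0, 1, 2, 3]

    def test_chain_keeps_top(self):
        pts = [(1, 1), (2, 2), (3, 3)]
        assert nondominated_filter(pts, MAX2) == [2]

    def test_matches_bruteforce_on_random_sets(self, rng):
        spec = ObjectiveSpec(("max", "min", "max"))
        for _ in range(500):
            pts = [tuple(rng.integers(0, 5, 3).tolist()) for _ in range(int(rng.integers(1, 12)))]
            assert nondominated_filter(pts, spec) == brute_nondominated(pts, spec)


class TestReduceArchive:
    def _archive(self, vectors):
        arch = Archive(spec=MAX2, soft_limit=100, hard_limit=50)
        arch.members = [(f"s{i}", np.asarray(v, float)) for i, v in enumerate(vectors)]
        return arch

    def test_no_reduction_needed(self):
        arch = self._archive([(1, 3), (3, 1)])
        assert len(reduce_archive(arch, 2).members) == 2

    def test_two_clumps_one_representative_each(self, rng):
        clump_a = [(1 + rng.normal(0, 1e-3), 10 + rng.normal(0, 1e-3)) for _ in range(5)]
        clump_b = [(10 + rng.normal(0, 1e-3), 1 + rng.normal(0, 1e-3)) for _ in range(5)]
        arch = self._archive(clump_a + clump_b)
        out = reduce_archive(arch, 2)
        objs = out.objective_matrix()
        assert len(out.members) == 2
        assert {int(o[0] > 5) for o in objs} == {0, 1}  # one from each clump

    def test_reduction_preserves_nondomination(self, rng):
        # mutually non-dominated front points
        xs = np.sort(rng.uniform(0, 1, 12))
        vectors = [(x, 1 - x) for x in xs]
        arch = self._archive(vectors)
        out = reduce_archive(arch, 5)
        objs = [tuple(o) for _, o in out.members]
        assert nondominated_filter(objs, MAX2) == list(range(5))

    def test_bad_target(self):
        with pytest.raises(ValueError):
            reduce_archive(self._archive([(1, 2), (2, 1)]), 0)


class ToyFrontProblem:
    """Maximize (x, 1-x^2) on [0,1]: every feasible x is Pareto-optimal."""

    objective_spec = ObjectiveSpec(("max", "max"))

    def random_solution(self, rng):
        return float(rng.uniform(0, 1))

    def mutate(self, x, rng):
        return float(np.clip(x + rng.normal(0, 0.1), 0.0, 1.0))

    def evaluate(self, x):
        return np.array([x, 1.0 - x * x])


class TestAnneal:
    CONFIG = AmosaConfig(soft_limit=30, hard_limit=15, iter_per_temp=10,
                         t_max=10.0, t_min=0.01, alpha=0.8, gamma=1.5)

    def test_temperature_level_count(self):
        config = AmosaConfig()  # published schedule
        assert config.n_temperature_levels() == 153

    def test_toy_front_recovered(self):
        arch = anneal(ToyFrontProblem(), self.CONFIG, np.random.default_rng(1))
        objs = arch.objective_matrix()
        residual = np.abs(objs[:, 1] - (1.0 - objs[:, 0] ** 2))
        assert np.mean(residual < 1e-2) >= 0.95

    def test_archive_mutually_nondominated_and_bounded(self):
        arch = anneal(ToyFrontProblem(), self.CONFIG, np.random.default_rng(2))
        assert len(arch.members) <= self.CONFIG.soft_limit
        objs = [tuple(o) for _, o in arch.members]
        assert nondominated_filter(objs, MAX2) == list(range(len(objs)))

    def test_deterministic_per_seed(self):
        a = anneal(ToyFrontProblem(), self.CONFIG, np.random.default_rng(7))
        b = anneal(ToyFrontProblem(), self.CONFIG, np.random.default_rng(7))
        np.testing.assert_array_equal(a.objective_matrix(), b.objective_matrix())


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"soft_limit": 10, "hard_limit": 10},
        {"alpha": 1.0},
        {"t_max": 1e-6},
        {"gamma": 1.0},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AmosaConfig(**kwargs)
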