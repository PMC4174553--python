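"""Validity indices against pair-enumeration oracles and hand-worked cases."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from feaclusmoo.validity_indices import (
    DegenerateSolutionError,
    adjusted_rand,
    minkowski_score,
    pair_counts,
    sym_index,
    xb_index,
)


def enumerate_pair_counts(t, s):
    """Oracle: explicit loop over all n(n-1)/2 pairs."""
    t, s = np.asarray(t), np.asarray(s)
    n11 = n01 = n10 = n00 = 0
    for i, j in itertools.combinations(range(len(t)), 2):
        same_t, same_s = t[i] == t[j], s[i] == s[j]
        if same_t and same_s:
            n11 += 1
        elif same_s:
            n01 += 1
        elif same_t:
            n10 += 1
        else:
            n00 += 1
    return n11, n01, n10, n00


def ari_from_pairs(t, s):
    """Independent pair-counting formulation of the adjusted Rand index."""
    n11, n01, n10, n00 = enumerate_pair_counts(t, s)
    total = n11 + n01 + n10 + n00
    a, b = n11 + n10, n11 + n01
    expected = a * b / total
    max_index = (a + b) / 2
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


class TestPairCounts:
    def test_three_point_example(self):
        pc = pair_counts([1, 1, 2], [1, 2, 2])
        assert (pc.n11, pc.n01, pc.n10, pc.n00) == (0, 1, 1, 1)

    def test_identical_partitions_have_no_disagreement(self):
        pc = pair_counts([0, 1, 1, 2, 0], [0, 1, 1, 2, 0])
        assert pc.n01 == pc.n10 == 0

    def test_all_singletons(self):
        pc = pair_counts([0, 1, 2, 3], [3, 2, 1, 0])
        assert (pc.n11, pc.n01, pc.n10) == (0, 0, 0)

    def test_counts_sum_to_all_pairs(self, rng):
        for _ in range(30):
            n = int(rng.integers(2, 16))
            t = rng.integers(0, 4, n)
            s = rng.integers(0, 4, n)
            pc = pair_counts(t, s)
            assert pc.n11 + pc.n01 + pc.n10 + pc.n00 == n * (n - 1) // 2
            assert (pc.n11, pc.n01, pc.n10, pc.n00) == enumerate_pair_counts(t, s)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pair_counts([0, 1], [0, 1, 2])


class TestMinkowskiScore:
    def test_identical_partitions_score_zero(self):
        assert minkowski_score([0, 0, 1, 2], [5, 5, 7, 9]) == 0.0

    def test_three_point_example(self):
        assert minkowski_score([1, 1, 2], [1, 2, 2]) == pytest.approx(np.sqrt(2))

    def test_single_pair(self):
        assert minkowski_score([1, 1], [1, 2]) == pytest.approx(1.0)

    def test_undefined_without_coclustered_reference_pair(self):
        with pytest.raises(ValueError):
            minkowski_score([0, 1, 2], [0, 0, 0])

    def test_asymmetric_in_arguments(self):
        # T all-singletons swaps n01/n10 roles and changes the denominator
        t, s = [1, 1, 2], [1, 2, 2]
        assert minkowski_score(t, s) == pytest.approx(np.sqrt(2))
        assert minkowski_score(s, t) == pytest.approx(np.sqrt(2))
        t2, s2 = [1, 1, 1], [1, 1, 2]
        assert minkowski_score(t2, s2) != pytest.approx(
            minkowski_score(s2, t2), abs=1e-12
        )

    def test_matches_pair_enumeration(self, rng):
        for _ in range(40):
            n = int(rng.integers(3, 16))
            t = rng.integers(0, 3, n)
            s = rng.integers(0, 3, n)
            n11, n01, n10, _ = enumerate_pair_counts(t, s)
            if n11 + n10 == 0:
                continue
            assert minkowski_score(t, s) == pytest.approx(
                np.sqrt((n01 + n10) / (n11 + n10)), abs=1e-12
            )


class TestAdjustedRand:
    def test_self_agreement_is_one(self, rng):
        labels = rng.integers(0, 4, 20)
        assert adjusted_rand(labels, labels) == 1.0

    def test_hand_contingency_example(self):
        assert adjusted_rand([1, 1, 2, 2], [1, 1, 1, 2]) == pytest.approx(0.0)

    def test_symmetric(self, rng):
        t = rng.integers(0, 3, 12)
        s = rng.integers(0, 3, 12)
        assert adjusted_rand(t, s) == pytest.approx(adjusted_rand(s, t), abs=1e-12)

    def test_matches_pair_enumeration_and_sklearn(self, rng):
        for _ in range(40):
            n = 12
            t = rng.integers(0, 4, n)
            s = rng.integers(0, 4, n)
            ours = adjusted_rand(t, s)
            assert ours == pytest.approx(ari_from_pairs(t, s), abs=1e-12)
            assert ours == pytest.approx(adjusted_rand_score(t, s), abs=1e-12)

    def test_degenerate_single_cluster_convention(self):
        assert adjusted_rand([0, 0, 0], [1, 1, 1]) == 1.0

    def test_ms_zero_iff_ari_one(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 15))
            t = rng.integers(0, 3, n)
            s = rng.integers(0, 3, n)
            if len(np.unique(t)) == n:
                continue
            ms_zero = minkowski_score(t, s) == 0.0
            ari_one = adjusted_rand(t, s) == pytest.approx(1.0)
            assert ms_zero == ari_one


class TestXbIndex:
    def test_two_pair_example(self):
        data = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], float)
        centers = np.array([[0, 0.5], [10, 0.5]])
        assert xb_index(data, [0, 0, 1, 1], centers) == pytest.approx(0.0025)

    def test_points_at_centers_give_zero(self):
        data = np.array([[0, 0], [5, 5], [9, 1]], float)
        assert xb_index(data, [0, 1, 2], data.copy()) == 0.0

    def test_scale_invariance(self, rng):
        data = rng.normal(size=(20, 3))
        labels = rng.integers(0, 2, 20)
        centers = rng.normal(size=(2, 3))
        xb = xb_index(data, labels, centers)
        s = 3.7
        assert xb_index(s * data, labels, s * centers) == pytest.approx(xb)

    def test_rigid_motion_invariance(self, rng):
        data = rng.normal(size=(15, 2))
        labels = rng.integers(0, 3, 15)
        centers = rng.normal(size=(3, 2))
        shift = np.array([100.0, -40.0])
        assert xb_index(data + shift, labels, centers + shift) == pytest.approx(
            xb_index(data, labels, centers), abs=1e-9
        )

    def test_coincident_centers_are_degenerate(self):
        data = np.array([[0, 0], [1, 1], [2, 2]], float)
        centers = np.array([[1, 1], [1, 1]])
        with pytest.raises(DegenerateSolutionError):
            xb_index(data, [0, 1, 1], centers)

    def test_active_subspace_only(self):
        # identical in the active feature; mask hides the differing one
        data = np.array([[0, 0], [0, 1], [10, 50], [10, 51]], float)
        centers = np.array([[0, 0.5], [10, 50.5]])
        masked = xb_index(data, [0, 0, 1, 1], centers, mask=[True, False])
        assert masked == pytest.approx(0.0)


class TestSymIndex:
    def test_two_cluster_hand_example(self):
        data = np.array([[0, 0], [2, 0], [10, 0], [12, 0]], float)
        centers = np.array([[1, 0], [11, 0]])
        # each point: reflection hits the partner exactly -> d_sym = (0+2)/2,
        # d_e = 1, so E_K = 4; D_K = 10
        assert sym_index(data, [0, 0, 1, 1], centers) == pytest.approx(1.25)

    def test_translation_invariance(self):
        data = np.array([[0, 0], [2, 0], [10, 0], [12, 0]], float)
        centers = np.array([[1, 0], [11, 0]])
        shift = np.array([-7.0, 3.0])
        assert sym_index(data + shift, [0, 0, 1, 1], centers + shift) == pytest.approx(
            1.25, abs=1e-9
        )

    def test_monotone_in_center_gap(self):
        data = np.array([[0, 0], [2, 0], [10, 0], [12, 0]], float)
        centers_far = np.array([[1, 0], [21, 0]])
        data_far = np.array([[0, 0], [2, 0], [20, 0], [22, 0]], float)
        assert sym_index(data_far, [0, 0, 1, 1], centers_far) > sym_index(
            data, [0, 0, 1, 1], np.array([[1, 0], [11, 0]])
        )

    def test_small_cluster_is_degenerate(self):
        data = np.array([[0, 0], [2, 0], [10, 0]], float)
        centers = np.array([[1, 0], [10, 0]])
        with pytest.raises(DegenerateSolutionError):
            sym_index(data, [0, 0, 1], centers)

    def test_empty_cluster_is_degenerate(self):
        data = np.array([[0, 0], [2, 0], [1, 1]], float)
        centers = np.array([[1, 0], [50, 50]])
        with pytest.raises(DegenerateSolutionError):
            sym_index(data, [0, 0, 0], centers)
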