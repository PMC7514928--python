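"""Distance definitions, linear-form identities and metric axioms."""

from itertools import permutations

import numpy as np
import pytest

from rankfuse import (
    RankMatrix,
    ValidationError,
    condorcet_distance,
    disagreement_distance,
    phi_condorcet,
    phi_disagreement,
    ranks_to_permutation_matrix,
    spearman_footrule,
    tally_pairs,
    tally_positions,
    theta_constant,
)

from .conftest import random_rank_matrix


def brute_disagreement(r, s):
    return sum(1 for a, b in zip(r, s) if abs(a - b) > 0)


def brute_condorcet(r, s):
    k = len(r)
    return sum(
        1
        for i in range(k)
        for j in range(i + 1, k)
        if np.sign(r[i] - r[j]) != np.sign(s[i] - s[j])
    )


class TestDistances:
    def test_zero_iff_equal(self):
        assert disagreement_distance([1, 2, 3], [1, 2, 3]) == 0
        assert condorcet_distance([1, 2, 3], [1, 2, 3]) == 0

    def test_small_cases(self):
        assert disagreement_distance([1, 2, 3], [2, 1, 3]) == 2
        assert condorcet_distance([1, 2, 3, 4], [4, 3, 2, 1]) == 6  # full reversal

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            disagreement_distance([1, 2], [1, 2, 3])
        with pytest.raises(ValidationError):
            condorcet_distance([1, 2], [1, 2, 3])

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 9))
            r = rng.permutation(k) + 1
            s = rng.permutation(k) + 1
            assert disagreement_distance(r, s) == brute_disagreement(r, s)
            assert condorcet_distance(r, s) == brute_condorcet(r, s)
            assert spearman_footrule(r, s) == int(np.abs(r - s).sum())

    def test_disagreement_never_one(self, rng):
        for _ in range(300):
            k = int(rng.integers(2, 7))
            d = disagreement_distance(rng.permutation(k) + 1, rng.permutation(k) + 1)
            assert d == 0 or 2 <= d <= k


class TestMetricAxioms:
    @pytest.mark.parametrize("dist", [disagreement_distance, condorcet_distance])
    def test_axioms_exhaustive_small_k(self, dist):
        for k in (2, 3, 4):
            perms = [np.array(p) + 1 for p in permutations(range(k))]
            for r in perms:
                for s in perms:
                    d = dist(r, s)
                    assert d >= 0
                    assert (d == 0) == np.array_equal(r, s)
                    assert d == dist(s, r)
            for r in perms:
                for s in perms:
                    for t in perms:
                        assert dist(r, t) <= dist(r, s) + dist(s, t)

    @pytest.mark.parametrize("dist", [disagreement_distance, condorcet_distance])
    def test_triangle_on_random_triples(self, dist, rng):
        for _ in range(200):
            k = int(rng.integers(5, 9))
            r, s, t = (rng.permutation(k) + 1 for _ in range(3))
            assert dist(r, t) <= dist(r, s) + dist(s, t)

    def test_inequality_chain_exhaustive_and_random(self, rng):
        # f_d <= footrule <= 2 f_C; the unfactored one-line form f_d <= f_C
        # fails on adjacent swaps, so the factor 2 is essential
        for k in (2, 3, 4):
            perms = [np.array(p) + 1 for p in permutations(range(k))]
            for r in perms:
                for s in perms:
                    assert (
                        disagreement_distance(r, s)
                        <= spearman_footrule(r, s)
                        <= 2 * condorcet_distance(r, s)
                    )
        for _ in range(500):
            k = int(rng.integers(2, 9))
            r = rng.permutation(k) + 1
            s = rng.permutation(k) + 1
            assert (
                disagreement_distance(r, s)
                <= spearman_footrule(r, s)
                <= 2 * condorcet_distance(r, s)
            )

    def test_adjacent_swap_breaks_unfactored_inequality(self):
        r, s = [1, 2, 3], [2, 1, 3]
        assert disagreement_distance(r, s) == 2
        assert condorcet_distance(r, s) == 1


class TestConsensusObjectives:
    def test_zero_at_unanimity(self):
        r = np.array([3, 1, 2])
        R = RankMatrix(np.column_stack([r] * 4))
        assert phi_disagreement(r, R) == 0
        assert phi_condorcet(r, R) == 0

    def test_distance_sum_equals_linear_form(self, rng):
        for _ in range(50):
            K = int(rng.integers(2, 8))
            M = int(rng.integers(1, 8))
            R = random_rank_matrix(rng, K, M)
            r = rng.permutation(K) + 1
            sum_d = sum(disagreement_distance(r, R.column(k)) for k in range(M))
            sum_c = sum(condorcet_distance(r, R.column(k)) for k in range(M))
            assert phi_disagreement(r, R) == sum_d
            assert phi_condorcet(r, R) == sum_c
            # tally-based linear forms
            pi = tally_positions(R)
            x = ranks_to_permutation_matrix(r).x
            assert sum_d == int(((M - pi.pi) * x).sum())
            delta = tally_pairs(R)
            y = (r[:, None] < r[None, :]).astype(int)
            assert sum_c == theta_constant(M, K) - int((delta.delta * y).sum())

    def test_duplicate_column_equal_to_r_adds_nothing(self, rng):
        K, M = 5, 4
        R = random_rank_matrix(rng, K, M)
        r = rng.permutation(K) + 1
        R2 = RankMatrix(np.column_stack([R.ranks, r]))
        assert phi_condorcet(r, R2) == phi_condorcet(r, R)
        assert phi_disagreement(r, R2) == phi_disagreement(r, R)

    def test_invariant_under_class_relabeling(self, rng):
        K, M = 6, 5
        R = random_rank_matrix(rng, K, M)
        r = rng.permutation(K) + 1
        perm = rng.permutation(K)
        Rp = R.relabel_classes(perm)
        assert phi_disagreement(r[perm], Rp) == phi_disagreement(r, R)
        assert phi_condorcet(r[perm], Rp) == phi_condorcet(r, R)
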