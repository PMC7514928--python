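"""Exact solvers: worked-example reproduction, oracle equivalence, tie-breaks."""

from itertools import permutations

import numpy as np
import pytest

from rankfuse import (
    CapabilityError,
    RankMatrix,
    enumerate_optima,
    phi_condorcet,
    phi_disagreement,
    solve_condorcet,
    solve_disagreement,
    theta_constant,
)
from rankfuse.consensus import _bnb_condorcet_optima, _order_to_ranks

from .conftest import random_rank_matrix


def brute_min_phi(R, phi):
    K = R.K
    return min(phi(np.array(p) + 1, R) for p in permutations(range(K)))


class TestDigitExample:
    """The four-classifier digit worked example, with its published consensus."""

    def test_disagreement_consensus(self, digit_example):
        res = solve_disagreement(digit_example)
        assert res.ranks.tolist() == [3, 2, 1, 4, 5, 6, 7, 8, 10, 9]
        assert res.objective == phi_disagreement(res.ranks, digit_example)

    def test_condorcet_consensus_with_tiebreak(self, digit_example):
        res = solve_condorcet(digit_example)
        assert res.ranks.tolist() == [3, 2, 1, 4, 6, 5, 7, 8, 10, 9]
        # digits 1 and 2 are majority-tied 2-2, so a tie-break must fire
        assert res.tiebreak_applied
        assert res.optimum_count == 2
        assert res.objective == phi_condorcet(res.ranks, digit_example)

    def test_metrics_disagree_exactly_on_digits_4_and_5(self, digit_example):
        d = solve_disagreement(digit_example).ranks
        c = solve_condorcet(digit_example).ranks
        diff = np.nonzero(d != c)[0].tolist()
        assert diff == [4, 5]


class TestTrivialInstances:
    def test_unanimous_ensemble_returns_the_shared_ranking(self, rng):
        r = rng.permutation(6) + 1
        R = RankMatrix(np.column_stack([r] * 5))
        d = solve_disagreement(R)
        c = solve_condorcet(R)
        assert np.array_equal(d.ranks, r) and d.objective == 0
        assert np.array_equal(c.ranks, r) and c.objective == 0
        # the maximized pairwise-vote score saturates at theta
        assert c.score == theta_constant(5, 6)
        assert d.optimum_count == 1 and c.optimum_count == 1

    def test_single_classifier_is_its_own_consensus(self, rng):
        r = rng.permutation(5) + 1
        R = RankMatrix(r[:, None])
        for solve in (solve_disagreement, solve_condorcet):
            res = solve(R)
            assert np.array_equal(res.ranks, r)
            assert res.objective == 0


class TestOracleEquivalence:
    """Both solvers must match exhaustive search over all K! permutations."""

    def test_objectives_match_brute_force(self, rng):
        for _ in range(60):
            K = int(rng.integers(2, 8))
            M = int(rng.integers(2, 10))
            R = random_rank_matrix(rng, K, M)
            assert solve_disagreement(R).objective == brute_min_phi(R, phi_disagreement)
            assert solve_condorcet(R).objective == brute_min_phi(R, phi_condorcet)

    def test_branch_and_bound_matches_exhaustive_at_k9(self, rng):
        # K = 9 is above the exhaustive ceiling, so solve_condorcet takes the
        # branch-and-bound path; compare against a vectorized sweep of all 9!
        # orders built independently in this test
        from itertools import chain

        from rankfuse import tally_pairs, theta_constant

        K = 9
        all_perms = np.fromiter(
            chain.from_iterable(permutations(range(K))), dtype=np.int8
        ).reshape(-1, K)
        for _ in range(3):
            R = random_rank_matrix(rng, K, 4)
            delta = tally_pairs(R).delta
            scores = np.zeros(all_perms.shape[0], dtype=np.int64)
            for i in range(K):
                for j in range(K):
                    if i != j and delta[i, j]:
                        scores += delta[i, j] * (all_perms[:, i] < all_perms[:, j])
            res = solve_condorcet(R)
            assert res.score == int(scores.max())
            assert res.objective == theta_constant(4, K) - int(scores.max())

    def test_bnb_helper_agrees_with_enumeration(self, rng):
        from rankfuse import tally_pairs

        for _ in range(10):
            K = int(rng.integers(3, 7))
            R = random_rank_matrix(rng, K, 3)
            delta = tally_pairs(R).delta
            best, orders, truncated = _bnb_condorcet_optima(delta)
            assert not truncated
            opt = enumerate_optima(R, "condorcet", cap=100000)
            assert len(orders) == len(opt)
            got = sorted(tuple(_order_to_ranks(o, K)) for o in orders)
            want = sorted(tuple(r) for r in opt)
            assert got == want


class TestStructuralInvariances:
    def test_duplicating_columns_doubles_objectives_keeps_optimum(self, rng):
        R = random_rank_matrix(rng, 6, 4)
        R2 = RankMatrix(np.column_stack([R.ranks, R.ranks]))
        for solve in (solve_disagreement, solve_condorcet):
            a, b = solve(R), solve(R2)
            assert b.objective == 2 * a.objective
            assert np.array_equal(a.ranks, b.ranks)

    def test_relabeling_classes_permutes_consensus(self, rng):
        R = random_rank_matrix(rng, 6, 5)
        perm = rng.permutation(6)
        Rp = R.relabel_classes(perm)
        for solve in (solve_disagreement, solve_condorcet):
            a, b = solve(R), solve(Rp)
            # objective is label-invariant; the ranking may differ only among co-optima
            assert b.objective == a.objective
            assert b.objective == (
                phi_disagreement(b.ranks, Rp) if solve is solve_disagreement else phi_condorcet(b.ranks, Rp)
            )

    def test_capability_error_above_ceiling(self, rng):
        R = random_rank_matrix(rng, 16, 3)
        with pytest.raises(CapabilityError):
            solve_condorcet(R)
        # the assignment solver has no such ceiling
        assert solve_disagreement(R).objective >= 0


class TestEnumerateOptima:
    def test_unanimous_profile_has_single_optimum(self, rng):
        r = rng.permutation(5) + 1
        R = RankMatrix(np.column_stack([r] * 3))
        for metric in ("disagreement", "condorcet"):
            opt = enumerate_optima(R, metric, cap=10)
            assert len(opt) == 1 and np.array_equal(opt[0], r)

    def test_digit_example_too_large_for_enumeration(self, digit_example):
        with pytest.raises(CapabilityError):
            enumerate_optima(digit_example, "condorcet")

    def test_majority_tied_pair_gives_two_optima(self):
        # two orders reversed on one adjacent pair: that pair is tied 1-1
        R = RankMatrix(np.column_stack([[1, 2, 3], [2, 1, 3]]))
        opt = enumerate_optima(R, "condorcet", cap=10)
        assert len(opt) == 2
        # lexicographic order of rank vectors; cap=1 returns the smallest
        assert opt[0].tolist() == [1, 2, 3]
        assert enumerate_optima(R, "condorcet", cap=1)[0].tolist() == [1, 2, 3]

    def test_optima_all_attain_the_optimal_objective(self, rng):
        for _ in range(10):
            K = int(rng.integers(3, 7))
            R = random_rank_matrix(rng, K, int(rng.integers(2, 6)))
            for metric, phi, solve in (
                ("disagreement", phi_disagreement, solve_disagreement),
                ("condorcet", phi_condorcet, solve_condorcet),
            ):
                best = solve(R).objective
                opt = enumerate_optima(R, metric, cap=100000)
                assert all(phi(r, R) == best for r in opt)

    def test_disagreement_tiebreak_is_lexicographic(self, rng):
        for _ in range(20):
            K = int(rng.integers(3, 7))
            R = random_rank_matrix(rng, K, int(rng.integers(2, 5)))
            res = solve_disagreement(R)
            opt = enumerate_optima(R, "disagreement", cap=100000)
            assert tuple(res.ranks) == min(tuple(r) for r in opt)
            assert res.optimum_count == len(opt)
            assert res.tiebreak_applied == (len(opt) > 1)
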