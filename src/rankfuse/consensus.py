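"""Globally optimal consensus-ranking solvers.

Both consensus problems are binary linear programs over the ensemble tallies:

* **Disagreement** — minimize ``sum_ij (M - pi[i,j]) x[i,j]`` over permutation
  matrices x.  The feasible set is the assignment polytope, whose vertices are
  exactly the permutation matrices, so the BLP relaxes exactly to a linear
  assignment problem: solved in polynomial time with the Hungarian-type solver
  in :func:`scipy.optimize.linear_sum_assignment`.  Exactness is guaranteed by
  LP duality (total unimodularity of the assignment constraints).

* **Condorcet** — maximize ``sum_ij delta[i,j] y[i,j]`` over binary y encoding
  a total order (zero diagonal, ``y[i,j] + y[j,i] = 1``, transitivity
  ``y[i,j] + y[j,k] - y[i,k] <= 1``).  This is the linear ordering problem
  (equivalently Kemeny aggregation), NP-hard in general.  At the scale this
  package targets it is solved exactly: exhaustive vectorized enumeration of
  all K! orders for K <= 8, and branch-and-bound over prefix orders with the
  admissible bound ``sum over unresolved pairs of max(delta[i,j], delta[j,i])``
  for 8 < K <= 15.  Larger K raises :class:`CapabilityError` — there is no
  silent heuristic fallback.

Tie-breaking is deterministic and auditable:

* disagreement: among optimal assignments, the lexicographically smallest
  rank vector;
* condorcet: among optimal orders, first maximize the position-vote score
  ``sum_i pi[i, r_i]`` (so the order most supported by outright placement
  votes wins), then the lexicographically smallest rank vector.  The
  secondary vote score matters exactly when a class pair is majority-tied.
"""

from __future__ import annotations

from itertools import permutations
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import ConsensusResult, RankMatrix, tally_pairs, tally_positions
from .exceptions import CapabilityError, ValidationError
from .metrics import theta_constant

__all__ = [
    "solve_disagreement",
    "solve_condorcet",
    "enumerate_optima",
    "EXHAUSTIVE_MAX_K",
    "BRANCH_AND_BOUND_MAX_K",
]

EXHAUSTIVE_MAX_K = 8
BRANCH_AND_BOUND_MAX_K = 15

# branch-and-bound optimum collection is capped; beyond the cap the optimum
# count is reported as None and the tie-break acts on the collected subset
_BNB_OPTIMA_CAP = 50_000


def _perm_array(K: int) -> np.ndarray:
    """All K! rank vectors as a (K!, K) array of 0-based positions, lexicographic."""
    return np.array(list(permutations(range(K))), dtype=np.int64)


def _position_scores(perms: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Vectorized ``sum_i pi[i, r_i]`` for every rank vector in ``perms``."""
    K = perms.shape[1]
    return pi[np.arange(K)[None, :], perms].sum(axis=1)


def _pair_scores(perms: np.ndarray, delta: np.ndarray) -> np.ndarray:
    """Vectorized ``sum_ij delta[i,j] [r_i < r_j]`` for every rank vector."""
    K = perms.shape[1]
    scores = np.zeros(perms.shape[0], dtype=np.int64)
    for i in range(K):
        for j in range(K):
            if i != j and delta[i, j]:
                scores += delta[i, j] * (perms[:, i] < perms[:, j])
    return scores


def solve_disagreement(R: RankMatrix) -> ConsensusResult:
    """Exact consensus under the disagreement (Hamming) metric.

    Minimizes ``phi_d(r) = sum_k f_d(r, r^(k))`` by solving the linear
    assignment problem on cost ``M - pi``.  Ties are broken toward the
    lexicographically smallest rank vector by greedy optimal fixing.
    """
    pi = tally_positions(R)
    cost = pi.cost()
    K, M = pi.K, pi.M

    rows, cols = linear_sum_assignment(cost)
    best = int(cost[rows, cols].sum())

    # lexicographic tie-break: fix classes 0..K-1 in turn to the smallest
    # position that preserves global optimality of the remainder
    assigned = np.full(K, -1, dtype=np.int64)
    free_cols = list(range(K))
    remaining_rows = list(range(K))
    fixed_cost = 0
    tiebreak = False
    for i in range(K):
        remaining_rows.remove(i)
        feasible = []
        for j in free_cols:
            sub = cost[np.ix_(remaining_rows, [c for c in free_cols if c != j])]
            sub_opt = int(sub[linear_sum_assignment(sub)].sum()) if remaining_rows else 0
            if fixed_cost + int(cost[i, j]) + sub_opt == best:
                feasible.append(j)
        if len(feasible) > 1:
            tiebreak = True
        j = min(feasible)
        assigned[i] = j
        free_cols.remove(j)
        fixed_cost += int(cost[i, j])

    ranks = assigned + 1
    score = int(pi.pi[np.arange(K), assigned].sum())
    count = None
    if K <= EXHAUSTIVE_MAX_K:
        perms = _perm_array(K)
        s = _position_scores(perms, pi.pi)
        count = int(np.count_nonzero(s == s.max()))
        tiebreak = count > 1
    return ConsensusResult(
        ranks=ranks,
        objective=best,
        score=score,
        metric="disagreement",
        optimum_count=count,
        tiebreak_applied=tiebreak,
        class_labels=R.class_labels,
    )


def _bnb_condorcet_optima(delta: np.ndarray, cap: int = _BNB_OPTIMA_CAP) -> tuple[int, list[tuple[int, ...]], bool]:
    """All maximizers of the pairwise-vote score, by branch-and-bound.

    Builds preference orders class-by-class from rank 1 downward.  Placing
    class c next adds ``sum_{u unplaced} delta[c, u]``; the admissible bound
    on the remainder is ``sum_{unordered unplaced pairs} max(delta, delta.T)``.

    Returns (best score, orders attaining it as tuples of 0-based class
    indices in preference order, truncated flag).
    """
    K = delta.shape[0]
    maxpair = np.maximum(delta, delta.T)

    best = -1
    optima: list[tuple[int, ...]] = []
    truncated = False

    full_mask = (1 << K) - 1
    # precomputed per-class row sums against a mask are rebuilt on the fly;
    # K <= 15 keeps this cheap
    order: list[int] = []

    def bound_remaining(mask: int) -> int:
        idx = [i for i in range(K) if mask >> i & 1]
        if len(idx) < 2:
            return 0
        sub = maxpair[np.ix_(idx, idx)]
        return int(np.triu(sub, 1).sum())

    def rec(mask: int, score: int) -> None:
        nonlocal best, truncated
        if mask == 0:
            if score > best:
                best = score
                optima.clear()
                optima.append(tuple(order))
            elif score == best:
                if len(optima) < cap:
                    optima.append(tuple(order))
                else:
                    truncated = True
            return
        if score + bound_remaining(mask) < best:
            return
        for c in range(K):
            if not (mask >> c & 1):
                continue
            rest = mask & ~(1 << c)
            gain = sum(int(delta[c, u]) for u in range(K) if rest >> u & 1)
            order.append(c)
            rec(rest, score + gain)
            order.pop()

    rec(full_mask, 0)
    return best, optima, truncated


def _order_to_ranks(order: Sequence[int], K: int) -> np.ndarray:
    """Preference order (class indices, best first) -> 1-based rank vector."""
    r = np.empty(K, dtype=np.int64)
    for pos, c in enumerate(order):
        r[c] = pos + 1
    return r


def solve_condorcet(R: RankMatrix) -> ConsensusResult:
    """Exact consensus under the Condorcet (Kendall) metric.

    Maximizes the pairwise-vote score over all total orders, which minimizes
    ``phi_C(r) = theta - score``.  Global optimality holds for K <= 15; above
    that a :class:`CapabilityError` is raised.

    Among co-optimal orders the one with the largest position-vote score
    ``sum_i pi[i, r_i]`` is returned, with any residual tie broken toward the
    lexicographically smallest rank vector.
    """
    delta = tally_pairs(R)
    pi = tally_positions(R)
    K, M = delta.K, delta.M
    theta = theta_constant(M, K)

    if K <= EXHAUSTIVE_MAX_K:
        perms = _perm_array(K)
        scores = _pair_scores(perms, delta.delta)
        best = int(scores.max())
        opt = perms[scores == best]
        count: int | None = opt.shape[0]
        truncated = False
    elif K <= BRANCH_AND_BOUND_MAX_K:
        best, orders, truncated = _bnb_condorcet_optima(delta.delta)
        opt = np.array([_order_to_ranks(o, K) - 1 for o in orders], dtype=np.int64)
        count = None if truncated else opt.shape[0]
    else:
        raise CapabilityError(
            f"Condorcet consensus for K={K} exceeds the exact-solver ceiling "
            f"(exhaustive K <= {EXHAUSTIVE_MAX_K}, branch-and-bound K <= {BRANCH_AND_BOUND_MAX_K})"
        )

    tiebreak = opt.shape[0] > 1
    if tiebreak:
        vote = _position_scores(opt, pi.pi)
        opt = opt[vote == vote.max()]
        if opt.shape[0] > 1:
            # lexicographically smallest rank vector
            idx = np.lexsort(opt[:, ::-1].T)
            opt = opt[idx[:1]]
    ranks = opt[0] + 1
    return ConsensusResult(
        ranks=ranks,
        objective=theta - best,
        score=best,
        metric="condorcet",
        optimum_count=count,
        tiebreak_applied=tiebreak,
        class_labels=R.class_labels,
    )


def enumerate_optima(R: RankMatrix, metric: str, cap: int = 1000) -> list[np.ndarray]:
    """All optimal rank vectors for the chosen metric, lexicographically sorted.

    Exhaustive over S_K, hence restricted to K <= 8; larger K raises
    :class:`CapabilityError`.  At most ``cap`` optima are returned (the
    lexicographically smallest ones).
    """
    if metric not in ("disagreement", "condorcet"):
        raise ValidationError(f"unknown metric {metric!r}")
    K = R.K
    if K > EXHAUSTIVE_MAX_K:
        raise CapabilityError(f"optimum enumeration requires K <= {EXHAUSTIVE_MAX_K}, got K={K}")
    perms = _perm_array(K)  # already lexicographic
    if metric == "disagreement":
        scores = _position_scores(perms, tally_positions(R).pi)
    else:
        scores = _pair_scores(perms, tally_pairs(R).delta)
    opt = perms[scores == scores.max()]
    return [row + 1 for row in opt[:cap]]
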