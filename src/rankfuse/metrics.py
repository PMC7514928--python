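"""Inter-ranking distances and ensemble consensus objectives.

Two metrics on the symmetric group S_K:

* disagreement distance ``f_d`` — the number of classes the two rankings put
  at different positions (Hamming distance between rank vectors);
* Condorcet distance ``f_C`` — the number of class pairs whose relative order
  the two rankings invert (Kendall tau distance).

For an ensemble R of M rankings the consensus objectives are
``phi_d(r) = sum_k f_d(r, r^(k))`` and ``phi_C(r) = sum_k f_C(r, r^(k))``.
Both admit linear forms in the ensemble tallies:

    phi_d(r) = sum_ij (M - pi[i,j]) x[i,j]        (x = permutation matrix of r)
    phi_C(r) = theta - sum_ij delta[i,j] y[i,j]   (y = pair matrix of r)

with the constant ``theta = M*K*(K-1)/2 = sum_ij delta[i,j]``.  These linear
forms are what the consensus solvers optimize; the equivalence with the
distance sums is exercised in the test suite.

All values are exact integers.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import (
    PairTally,
    PositionTally,
    RankMatrix,
    tally_pairs,
    tally_positions,
    validate_rank_vector,
)
from .exceptions import ValidationError

__all__ = [
    "disagreement_distance",
    "condorcet_distance",
    "spearman_footrule",
    "phi_disagreement",
    "phi_condorcet",
    "theta_constant",
    "vote_score_positions",
    "vote_score_pairs",
]


def _pair(r: Sequence[int], s: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    a = validate_rank_vector(r, name="first ranking")
    b = validate_rank_vector(s, name="second ranking")
    if a.size != b.size:
        raise ValidationError(f"rankings have different lengths: {a.size} vs {b.size}")
    return a, b


def disagreement_distance(r: Sequence[int], s: Sequence[int]) -> int:
    """Number of classes placed at different positions by the two rankings.

    Takes values in {0} U {2, ..., K}: two total orders cannot differ at
    exactly one position.
    """
    a, b = _pair(r, s)
    return int(np.count_nonzero(a != b))


def condorcet_distance(r: Sequence[int], s: Sequence[int]) -> int:
    """Number of discordant class pairs (Kendall tau distance).

    0 iff the rankings coincide; K*(K-1)/2 at full reversal.
    """
    a, b = _pair(r, s)
    ya = a[:, None] < a[None, :]
    yb = b[:, None] < b[None, :]
    return int(np.count_nonzero(ya & ~yb))


def spearman_footrule(r: Sequence[int], s: Sequence[int]) -> int:
    """Total absolute rank displacement ``sum_i |r_i - s_i|``.

    Not a consensus metric here; it is the middle term of the chain
    ``f_d <= footrule <= 2 * f_C`` relating the two metrics.
    """
    a, b = _pair(r, s)
    return int(np.abs(a - b).sum())


def theta_constant(M: int, K: int) -> int:
    """The constant ``theta = M*K*(K-1)/2`` linking phi_C to the pairwise vote score.

    Equals the total pair tally ``sum_ij delta[i,j]``; for any total order y,
    ``phi_C(r) = theta - sum_ij delta[i,j]*y[i,j]``.
    """
    return M * K * (K - 1) // 2


def vote_score_positions(r: Sequence[int], pi: PositionTally) -> int:
    """Position-vote score ``sum_i pi[i, r_i]`` — votes agreeing with each placement."""
    arr = validate_rank_vector(r)
    if arr.size != pi.K:
        raise ValidationError(f"ranking length {arr.size} != tally dimension {pi.K}")
    return int(pi.pi[np.arange(arr.size), arr - 1].sum())


def vote_score_pairs(r: Sequence[int], delta: PairTally) -> int:
    """Pairwise-vote score ``sum_ij delta[i,j] * y[i,j]`` for the order induced by r."""
    arr = validate_rank_vector(r)
    if arr.size != delta.K:
        raise ValidationError(f"ranking length {arr.size} != tally dimension {delta.K}")
    y = arr[:, None] < arr[None, :]
    return int(delta.delta[y].sum())


def phi_disagreement(r: Sequence[int], R: RankMatrix | PositionTally) -> int:
    """Consensus objective under the disagreement metric.

    ``phi_d(r) = sum_k f_d(r, r^(k)) = M*K - sum_i pi[i, r_i]``.
    Accepts either the full rank matrix or its position tally.
    """
    pi = R if isinstance(R, PositionTally) else tally_positions(R)
    arr = validate_rank_vector(r)
    if arr.size != pi.K:
        raise ValidationError(f"ranking length {arr.size} != ensemble class count {pi.K}")
    return pi.M * pi.K - vote_score_positions(arr, pi)


def phi_condorcet(r: Sequence[int], R: RankMatrix | PairTally) -> int:
    """Consensus objective under the Condorcet metric.

    ``phi_C(r) = sum_k f_C(r, r^(k)) = theta - sum_ij delta[i,j]*y[i,j]``.
    Accepts either the full rank matrix or its pair tally.
    """
    delta = R if isinstance(R, PairTally) else tally_pairs(R)
    arr = validate_rank_vector(r)
    if arr.size != delta.K:
        raise ValidationError(f"ranking length {arr.size} != ensemble class count {delta.K}")
    return theta_constant(delta.M, delta.K) - vote_score_pairs(arr, delta)
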