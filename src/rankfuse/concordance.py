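"""Conjunction (agreement) coefficients for a rank-classifier ensemble.

Analogues of Kendall's coefficient of concordance built from the ensemble
tallies rather than from rank sums, one per consensus metric:

* ``I_C`` (Condorcet): the fraction of agreeing classifier pairs on ordered
  class pairs, rescaled to reach 1 at unanimity,

      I_C = 4 * sum_ij delta[i,j] * (delta[i,j] - 1) / (M*(M-1)*K*(K-1)) - 1.

  For each ordered class pair, ``delta*(delta-1)`` counts ordered classifier
  pairs that agree on it; the normalizer is the count at unanimity.

* ``I_d`` (disagreement): the positional analogue,

      I_d = sum_ij pi[i,j] * (pi[i,j] - 1) / (K*M*(M-1)),

  the probability that two distinct classifiers drawn at random place a
  random class at the same position, normalized to 1 at unanimity.  This
  construction mirrors the pair-counting form of ``I_C`` position-wise; it is
  1 iff all rankings are identical and 0 iff no (class, position) cell
  receives two votes, and always lies in [0, 1].

Attainable ranges: ``I_d`` spans [0, 1].  ``I_C`` reaches 1 only at
unanimity; its minimum is set by the most balanced pair tally,
``-1/(M-1)`` for even M and ``-1/M`` for odd M (:func:`ic_bounds`).  A
parity-swapped variant of this interval circulates; both conventions are
exposed and the enumeration-backed one is the default (see
:func:`enumerate_coefficient_range` for the exhaustive check at small M, K).

Numerators are accumulated in exact integer arithmetic; a single division
produces the coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations, product

import numpy as np

from .core import PairTally, PositionTally, RankMatrix, tally_pairs, tally_positions
from .exceptions import ValidationError

__all__ = [
    "ConcordanceReport",
    "conjunction_condorcet",
    "conjunction_disagreement",
    "ic_bounds",
    "enumerate_coefficient_range",
]


@dataclass(frozen=True)
class ConcordanceReport:
    """An agreement coefficient with its attainable interval.

    ``lower_bound <= coefficient <= upper_bound`` (upper is always 1).
    """

    metric: str
    coefficient: float
    M: int
    K: int
    lower_bound: float
    upper_bound: float = 1.0

    def __post_init__(self) -> None:
        tol = 1e-12
        if not (self.lower_bound - tol <= self.coefficient <= self.upper_bound + tol):
            raise ValidationError(
                f"{self.metric} coefficient {self.coefficient} outside "
                f"[{self.lower_bound}, {self.upper_bound}]"
            )


def _as_pair_tally(source: PairTally | RankMatrix) -> PairTally:
    return source if isinstance(source, PairTally) else tally_pairs(source)


def _as_position_tally(source: PositionTally | RankMatrix) -> PositionTally:
    return source if isinstance(source, PositionTally) else tally_positions(source)


def conjunction_condorcet(D: PairTally | RankMatrix) -> ConcordanceReport:
    """Condorcet conjunction coefficient I_C of an ensemble.

    Requires M >= 2 (agreement between fewer than two classifiers is
    undefined).  Equals 1 iff all classifiers produce the identical ranking.
    """
    delta = _as_pair_tally(D)
    M, K = delta.M, delta.K
    if M < 2:
        raise ValidationError(f"conjunction coefficient undefined for M={M} < 2 classifiers")
    num = int((delta.delta * (delta.delta - 1)).sum())
    coeff = 4 * num / (M * (M - 1) * K * (K - 1)) - 1
    lower, upper = ic_bounds(M, K)
    return ConcordanceReport("condorcet", coeff, M, K, lower, upper)


def conjunction_disagreement(P: PositionTally | RankMatrix) -> ConcordanceReport:
    """Disagreement conjunction coefficient I_d of an ensemble.

    Requires M >= 2.  Lies in [0, 1]; 1 iff all rankings are identical, 0 iff
    every (class, position) cell collects at most one vote (e.g. cyclic
    shifts).
    """
    pi = _as_position_tally(P)
    M, K = pi.M, pi.K
    if M < 2:
        raise ValidationError(f"conjunction coefficient undefined for M={M} < 2 classifiers")
    num = int((pi.pi * (pi.pi - 1)).sum())
    coeff = num / (K * M * (M - 1))
    return ConcordanceReport("disagreement", coeff, M, K, 0.0, 1.0)


def ic_bounds(M: int, K: int, convention: str = "balanced") -> tuple[float, float]:
    """Attainable interval of I_C for M classifiers over K classes.

    The upper endpoint is 1 (unanimity).  The lower endpoint follows from the
    most balanced pair tally — splitting each class pair's M votes as evenly
    as possible minimizes ``sum delta*(delta-1)``:

    * M even: delta = M/2 everywhere off-diagonal gives I_C = -1/(M-1);
    * M odd: splits of (M+1)/2 vs (M-1)/2 give I_C = -1/M.

    This per-pair minimum bounds I_C below for *every* ensemble, realizable
    or not, and is attained by explicit profiles at small M, K (see
    :func:`enumerate_coefficient_range`).  ``convention="swapped"`` returns
    the parity-swapped variant of the interval (-1/M for even M, -1/(M-1)
    for odd M) for comparison; it is not supported by enumeration.
    """
    if M < 2 or K < 2:
        raise ValidationError(f"need M >= 2 and K >= 2, got M={M}, K={K}")
    if convention == "balanced":
        lower = -1.0 / (M - 1) if M % 2 == 0 else -1.0 / M
    elif convention == "swapped":
        lower = -1.0 / M if M % 2 == 0 else -1.0 / (M - 1)
    else:
        raise ValidationError(f"unknown convention {convention!r}")
    return lower, 1.0


def enumerate_coefficient_range(
    M: int, K: int, metric: str = "condorcet"
) -> tuple[float, float]:
    """Exact (min, max) of a conjunction coefficient over all (K!)^M profiles.

    Brute-force oracle for the interval claims; practical for K! ** M up to a
    few hundred thousand (e.g. M, K <= 4).
    """
    if metric not in ("condorcet", "disagreement"):
        raise ValidationError(f"unknown metric {metric!r}")
    orders = [np.array(p, dtype=np.int64) + 1 for p in permutations(range(K))]
    lo, hi = np.inf, -np.inf
    for profile in product(orders, repeat=M):
        R = RankMatrix(np.column_stack(profile))
        report = (
            conjunction_condorcet(R) if metric == "condorcet" else conjunction_disagreement(R)
        )
        lo = min(lo, report.coefficient)
        hi = max(hi, report.coefficient)
    return float(lo), float(hi)
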