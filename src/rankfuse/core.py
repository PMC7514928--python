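"""Domain types for total-order rankings and their tallies.

A rank classifier over K classes emits a *total order ranking*: a vector
``r`` assigning each class a distinct rank in 1..K, rank 1 being the most
likely class.  An ensemble of M such classifiers is held as a
:class:`RankMatrix` (K classes x M classifiers).

Three equivalent representations of a single ranking are supported, with
validated conversions between them:

* the rank vector ``r`` itself (1-based, length K);
* the permutation matrix ``x`` with ``x[i, j] = 1`` iff class i occupies
  position j (:class:`PermutationMatrix`);
* the pairwise-preference matrix ``y`` with ``y[i, j] = 1`` iff class i is
  ranked above (before) class j (:class:`PairPreferenceMatrix`).

Two tallies summarize an ensemble and are the sufficient statistics for the
two consensus problems:

* :class:`PositionTally` ``pi``, with ``pi[i, j]`` = number of classifiers
  placing class i at position j (drives the assignment consensus);
* :class:`PairTally` ``delta``, with ``delta[i, j]`` = number of classifiers
  preferring class i to class j (drives the linear-ordering consensus).

Ranks are 1-based at every public boundary; all internal matrix indices are
0-based.  Ties and partial orders are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "RankMatrix",
    "PermutationMatrix",
    "PairPreferenceMatrix",
    "PositionTally",
    "PairTally",
    "ConsensusResult",
    "validate_rank_vector",
    "ranks_to_permutation_matrix",
    "permutation_matrix_to_ranks",
    "ranks_to_pair_matrix",
    "pair_matrix_to_ranks",
    "tally_positions",
    "tally_pairs",
]


def validate_rank_vector(r: Sequence[int], name: str = "ranks") -> np.ndarray:
    """Check that ``r`` is a permutation of 1..K and return it as an int array.

    Raises :class:`ValidationError` naming the duplicated or missing rank.
    """
    arr = np.asarray(r)
    if arr.ndim != 1 or arr.size < 2:
        raise ValidationError(f"{name}: need a 1-d vector of length >= 2, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if np.issubdtype(arr.dtype, np.floating) and np.all(arr == np.floor(arr)):
            arr = arr.astype(np.int64)
        else:
            raise ValidationError(f"{name}: ranks must be integers, got dtype {arr.dtype}")
    arr = arr.astype(np.int64)
    k = arr.size
    counts = np.bincount(arr, minlength=k + 1)[1:] if arr.min() >= 0 else None
    if counts is None or arr.min() < 1 or arr.max() > k or not np.all(counts == 1):
        expected = set(range(1, k + 1))
        seen = set(int(v) for v in arr)
        missing = sorted(expected - seen)
        dup = sorted(v for v in seen if int(np.sum(arr == v)) > 1)
        extra = sorted(seen - expected)
        parts = []
        if dup:
            parts.append(f"duplicated rank(s) {dup}")
        if missing:
            parts.append(f"missing rank(s) {missing}")
        if extra:
            parts.append(f"out-of-range value(s) {extra}")
        raise ValidationError(f"{name}: not a permutation of 1..{k} ({'; '.join(parts)})")
    return arr


def _default_labels(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i}" for i in range(n)]


@dataclass(frozen=True)
class RankMatrix:
    """K x M matrix of ranks; column k is classifier k's total order of the K classes.

    Entry ``ranks[i, k]`` is the (1-based) rank that classifier k assigns to
    class i — smaller means more likely.  Every column must be a permutation
    of 1..K.
    """

    ranks: np.ndarray
    class_labels: tuple[str, ...] = ()
    classifier_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ranks = np.asarray(self.ranks)
        if ranks.ndim != 2:
            raise ValidationError(f"rank matrix must be 2-d (K x M), got shape {ranks.shape}")
        K, M = ranks.shape
        if K < 2 or M < 1:
            raise ValidationError(f"need K >= 2 classes and M >= 1 classifiers, got K={K}, M={M}")
        for k in range(M):
            validate_rank_vector(ranks[:, k], name=f"column {k}")
        object.__setattr__(self, "ranks", ranks.astype(np.int64))
        cls = tuple(self.class_labels) or tuple(_default_labels("class", K))
        clf = tuple(self.classifier_labels) or tuple(_default_labels("clf", M))
        if len(cls) != K:
            raise ValidationError(f"expected {K} class labels, got {len(cls)}")
        if len(clf) != M:
            raise ValidationError(f"expected {M} classifier labels, got {len(clf)}")
        if len(set(cls)) != K:
            raise ValidationError("class labels must be unique")
        if len(set(clf)) != M:
            raise ValidationError("classifier labels must be unique")
        object.__setattr__(self, "class_labels", cls)
        object.__setattr__(self, "classifier_labels", clf)

    @property
    def K(self) -> int:
        return self.ranks.shape[0]

    @property
    def M(self) -> int:
        return self.ranks.shape[1]

    def column(self, k: int) -> np.ndarray:
        """Rank vector of classifier k (1-based ranks)."""
        return self.ranks[:, k].copy()

    @classmethod
    def from_columns(
        cls,
        columns: Sequence[Sequence[int]],
        class_labels: Sequence[str] = (),
        classifier_labels: Sequence[str] = (),
    ) -> "RankMatrix":
        """Build from an iterable of rank vectors (one per classifier)."""
        ranks = np.column_stack([np.asarray(c) for c in columns])
        return cls(ranks, tuple(class_labels), tuple(classifier_labels))

    def relabel_classes(self, perm: Sequence[int]) -> "RankMatrix":
        """Reorder the class axis by ``perm`` (0-based positions into the old order)."""
        idx = np.asarray(perm)
        return RankMatrix(
            self.ranks[idx, :],
            tuple(self.class_labels[i] for i in idx),
            self.classifier_labels,
        )


@dataclass(frozen=True)
class PermutationMatrix:
    """K x K binary matrix with ``x[i, j] = 1`` iff class i occupies position j."""

    x: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x)
        if x.ndim != 2 or x.shape[0] != x.shape[1]:
            raise ValidationError(f"permutation matrix must be square, got shape {x.shape}")
        if not np.all((x == 0) | (x == 1)):
            raise ValidationError("permutation matrix entries must be 0/1")
        if not (np.all(x.sum(axis=0) == 1) and np.all(x.sum(axis=1) == 1)):
            raise ValidationError("permutation matrix rows and columns must each sum to 1")
        object.__setattr__(self, "x", x.astype(np.int64))

    @property
    def K(self) -> int:
        return self.x.shape[0]


@dataclass(frozen=True)
class PairPreferenceMatrix:
    """K x K binary matrix with ``y[i, j] = 1`` iff class i is preferred to class j.

    For a total order: zero diagonal, ``y + y.T`` all ones off-diagonal, and
    transitive.
    """

    y: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y)
        if y.ndim != 2 or y.shape[0] != y.shape[1]:
            raise ValidationError(f"pair-preference matrix must be square, got shape {y.shape}")
        if not np.all((y == 0) | (y == 1)):
            raise ValidationError("pair-preference entries must be 0/1")
        if np.any(np.diag(y) != 0):
            raise ValidationError("pair-preference diagonal must be 0")
        s = y + y.T
        off = ~np.eye(y.shape[0], dtype=bool)
        if not np.all(s[off] == 1):
            raise ValidationError("antisymmetry violated: need y[i,j] + y[j,i] = 1 for i != j")
        # transitivity <=> the tournament is acyclic <=> out-degrees are all distinct
        outdeg = y.sum(axis=1)
        if len(set(outdeg.tolist())) != y.shape[0]:
            raise ValidationError("pair-preference matrix is not transitive (contains a cycle)")
        object.__setattr__(self, "y", y.astype(np.int64))

    @property
    def K(self) -> int:
        return self.y.shape[0]


@dataclass(frozen=True)
class PositionTally:
    """Vote tally ``pi[i, j]`` = number of classifiers placing class i at position j.

    Both marginals equal M: each classifier puts exactly one class at each
    position and each class at exactly one position.  The assignment cost of
    placing class i at position j is ``M - pi[i, j]`` (the classifiers that
    voted otherwise).
    """

    pi: np.ndarray
    M: int

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi)
        if pi.ndim != 2 or pi.shape[0] != pi.shape[1]:
            raise ValidationError(f"position tally must be square, got shape {pi.shape}")
        if np.any(pi < 0) or np.any(pi > self.M):
            raise ValidationError(f"tally entries must lie in 0..M={self.M}")
        if not (np.all(pi.sum(axis=0) == self.M) and np.all(pi.sum(axis=1) == self.M)):
            raise ValidationError("position tally rows and columns must each sum to M")
        object.__setattr__(self, "pi", pi.astype(np.int64))

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    def cost(self) -> np.ndarray:
        """Assignment cost matrix ``M - pi``."""
        return self.M - self.pi


@dataclass(frozen=True)
class PairTally:
    """Vote tally ``delta[i, j]`` = number of classifiers preferring class i to class j.

    Zero diagonal and ``delta[i, j] + delta[j, i] = M`` for i != j, so the
    full sum is M*K*(K-1)/2.
    """

    delta: np.ndarray
    M: int

    def __post_init__(self) -> None:
        d = np.asarray(self.delta)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValidationError(f"pair tally must be square, got shape {d.shape}")
        if np.any(np.diag(d) != 0):
            raise ValidationError("pair tally diagonal must be 0")
        off = ~np.eye(d.shape[0], dtype=bool)
        if not np.all((d + d.T)[off] == self.M):
            raise ValidationError("need delta[i,j] + delta[j,i] = M for i != j")
        object.__setattr__(self, "delta", d.astype(np.int64))

    @property
    def K(self) -> int:
        return self.delta.shape[0]


@dataclass(frozen=True)
class ConsensusResult:
    """Outcome of a consensus solve.

    Attributes
    ----------
    ranks : ndarray
        The consensus rank vector (permutation of 1..K, 1-based).
    objective : int
        The minimized consensus function: the sum over classifiers of the
        chosen metric's distance from the consensus to each classifier's
        ranking.  Always >= 0.
    score : int
        The maximized binary-linear-program value the solver actually
        optimizes — the position-vote score ``sum pi[i, r_i]`` for the
        disagreement metric, the pairwise-vote score ``sum delta[i,j]*y[i,j]``
        for the Condorcet metric.  ``objective`` and ``score`` are affine
        transforms of each other at fixed tallies.
    metric : str
        ``"disagreement"`` or ``"condorcet"``.
    optimum_count : int or None
        Number of distinct optimal rankings, when known (None if the solver
        did not enumerate them, e.g. capped branch-and-bound).
    tiebreak_applied : bool
        True when more than one optimum existed and the deterministic
        tie-break rule selected among them.
    class_labels : tuple of str
        Labels aligned with ``ranks``.
    """

    ranks: np.ndarray
    objective: int
    score: int
    metric: str
    optimum_count: int | None = None
    tiebreak_applied: bool = False
    class_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        r = validate_rank_vector(self.ranks, name="consensus ranks")
        object.__setattr__(self, "ranks", r)
        if self.objective < 0:
            raise ValidationError("consensus objective must be >= 0")
        if not self.class_labels:
            object.__setattr__(self, "class_labels", tuple(_default_labels("class", r.size)))

    @property
    def K(self) -> int:
        return self.ranks.size

    def top_class(self) -> int:
        """0-based index of the class with consensus rank 1."""
        return int(np.argmin(self.ranks))

    def ranks_by_label(self) -> dict[str, int]:
        return {lab: int(r) for lab, r in zip(self.class_labels, self.ranks)}


# ---------------------------------------------------------------------------
# conversions


def ranks_to_permutation_matrix(r: Sequence[int]) -> PermutationMatrix:
    """Permutation-matrix representation: ``x[i, j] = 1`` iff ``r[i] == j+1``."""
    arr = validate_rank_vector(r)
    k = arr.size
    x = np.zeros((k, k), dtype=np.int64)
    x[np.arange(k), arr - 1] = 1
    return PermutationMatrix(x)


def permutation_matrix_to_ranks(P: PermutationMatrix | np.ndarray) -> np.ndarray:
    """Recover the rank vector ``r[i] = sum_j (j+1) * x[i, j]``."""
    if not isinstance(P, PermutationMatrix):
        P = PermutationMatrix(np.asarray(P))
    k = P.K
    return (P.x @ np.arange(1, k + 1, dtype=np.int64)).astype(np.int64)


def ranks_to_pair_matrix(r: Sequence[int]) -> PairPreferenceMatrix:
    """Pairwise representation: ``y[i, j] = 1`` iff class i outranks class j."""
    arr = validate_rank_vector(r)
    y = (arr[:, None] < arr[None, :]).astype(np.int64)
    return PairPreferenceMatrix(y)


def pair_matrix_to_ranks(Y: PairPreferenceMatrix | np.ndarray) -> np.ndarray:
    """Recover ranks from a transitive pair-preference matrix.

    A class preferred to ``w`` others has rank ``K - w``.
    """
    if not isinstance(Y, PairPreferenceMatrix):
        Y = PairPreferenceMatrix(np.asarray(Y))
    wins = Y.y.sum(axis=1)
    return (Y.K - wins).astype(np.int64)


# ---------------------------------------------------------------------------
# tallies


def tally_positions(R: RankMatrix) -> PositionTally:
    """Position tally: ``pi[i, j]`` = number of columns ranking class i at j+1."""
    K, M = R.K, R.M
    pi = np.zeros((K, K), dtype=np.int64)
    rows = np.repeat(np.arange(K), M)
    cols = (R.ranks - 1).ravel()
    np.add.at(pi, (rows, cols), 1)
    return PositionTally(pi, M)


def tally_pairs(R: RankMatrix) -> PairTally:
    """Pair tally: ``delta[i, j]`` = number of columns with class i ranked above j."""
    r = R.ranks  # K x M
    delta = (r[:, None, :] < r[None, :, :]).sum(axis=2).astype(np.int64)
    return PairTally(delta, R.M)
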