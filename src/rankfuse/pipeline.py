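"""Per-sample ensemble combination and evaluation.

An observation is classified by showing it to M rank classifiers, collecting
the M rank vectors into a K x M matrix, solving the chosen consensus problem,
and predicting the class the consensus ranks first.  A :class:`SampleBatch`
holds n such observations; :func:`combine_batch` maps the batch to
predictions and :func:`evaluate` scores them, with the false-positive and
false-negative rates computed against an explicitly designated positive
class — in the screening application the rare pathological class, where the
two error directions carry very different risk.

Also included are confusion-matrix diagnostics: the per-class rank
likelihoods ``p(ranked k-th | true class j)`` estimated as ``n_jk / n_j.``,
and an empirical independence gap between two classifiers' decision streams.
These are diagnostics only — the true classes needed to use them as a fusion
rule are unknown at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .consensus import solve_condorcet, solve_disagreement
from .core import ConsensusResult, RankMatrix
from .exceptions import ValidationError

__all__ = [
    "SampleBatch",
    "EvaluationReport",
    "ConfusionMatrix",
    "scores_to_ranks",
    "combine_batch",
    "evaluate",
    "rank_likelihoods",
    "pairwise_independence_gap",
    "binary_marginal_decision_probability",
]

_SOLVERS: dict[str, Callable[[RankMatrix], ConsensusResult]] = {
    "disagreement": solve_disagreement,
    "condorcet": solve_condorcet,
}


@dataclass(frozen=True)
class SampleBatch:
    """n observations, each with the M classifiers' rank vectors over K classes.

    ``rank_tensor[s]`` is the K x M rank matrix for sample s; every slice must
    satisfy the :class:`RankMatrix` invariants.  ``true_labels`` (0-based
    class indices) are optional; ``positive_class`` designates the class
    counted as "positive" for FPR/FNR.
    """

    rank_tensor: np.ndarray
    true_labels: np.ndarray | None = None
    positive_class: int | None = None
    class_labels: tuple[str, ...] = ()
    classifier_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.rank_tensor)
        if t.ndim != 3:
            raise ValidationError(f"rank tensor must be n x K x M, got shape {t.shape}")
        n, K, M = t.shape
        for s in range(n):
            try:
                RankMatrix(t[s], self.class_labels, self.classifier_labels)
            except ValidationError as e:
                raise ValidationError(f"sample {s}: {e}") from e
        object.__setattr__(self, "rank_tensor", t.astype(np.int64))
        if self.true_labels is not None:
            y = np.asarray(self.true_labels, dtype=np.int64)
            if y.shape != (n,):
                raise ValidationError(f"true labels must have shape ({n},), got {y.shape}")
            if y.size and (y.min() < 0 or y.max() >= K):
                raise ValidationError("true labels must be class indices in 0..K-1")
            object.__setattr__(self, "true_labels", y)
        if self.positive_class is not None and not (0 <= self.positive_class < K):
            raise ValidationError(f"positive class {self.positive_class} not in 0..{K - 1}")
        cls = tuple(self.class_labels) or tuple(f"class{i}" for i in range(K))
        clf = tuple(self.classifier_labels) or tuple(f"clf{i}" for i in range(M))
        object.__setattr__(self, "class_labels", cls)
        object.__setattr__(self, "classifier_labels", clf)

    @property
    def n(self) -> int:
        return self.rank_tensor.shape[0]

    @property
    def K(self) -> int:
        return self.rank_tensor.shape[1]

    @property
    def M(self) -> int:
        return self.rank_tensor.shape[2]

    def sample(self, s: int) -> RankMatrix:
        return RankMatrix(self.rank_tensor[s], self.class_labels, self.classifier_labels)


@dataclass(frozen=True)
class EvaluationReport:
    """Error rate and positive-class error rates over the labeled samples.

    ``fpr = FP / N`` (negatives predicted positive over all negatives) and
    ``fnr = FN / P`` (positives missed over all positives).  A rate whose
    denominator is zero is reported as NaN — undefined, not zero.
    """

    error_rate: float
    fpr: float
    fnr: float
    n_evaluated: int

    def __post_init__(self) -> None:
        for name in ("error_rate", "fpr", "fnr"):
            v = getattr(self, name)
            if not np.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} = {v} outside [0, 1]")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Counts ``n[j, k]``: how often true class j was ranked (k+1)-th by a classifier."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValidationError(f"confusion matrix must be square, got shape {c.shape}")
        if np.any(c < 0):
            raise ValidationError("confusion counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def K(self) -> int:
        return self.counts.shape[0]


def scores_to_ranks(scores: Sequence[float]) -> np.ndarray:
    """Convert a per-class score vector into a rank vector (highest score -> rank 1).

    Ties go to the smaller class index, so the conversion is deterministic.
    NaN scores are rejected.
    """
    s = np.asarray(scores, dtype=np.float64)
    if s.ndim != 1 or s.size < 2:
        raise ValidationError(f"need a 1-d score vector of length >= 2, got shape {s.shape}")
    if np.any(np.isnan(s)):
        raise ValidationError("scores contain NaN")
    order = np.lexsort((np.arange(s.size), -s))  # descending score, index tie-break
    ranks = np.empty(s.size, dtype=np.int64)
    ranks[order] = np.arange(1, s.size + 1)
    return ranks


def combine_batch(
    B: SampleBatch, metric: str = "condorcet"
) -> tuple[np.ndarray, list[ConsensusResult]]:
    """Consensus-combine every sample; predict the class with consensus rank 1.

    Returns (predictions as 0-based class indices, per-sample consensus
    results).  Each sample is solved independently — the consensus couples
    classifiers, not samples.
    """
    if metric not in _SOLVERS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {sorted(_SOLVERS)}")
    solve = _SOLVERS[metric]
    results = [solve(B.sample(s)) for s in range(B.n)]
    preds = np.array([res.top_class() for res in results], dtype=np.int64)
    return preds, results


def evaluate(
    predictions: Sequence[int],
    true_labels: Sequence[int],
    positive_class: int,
) -> EvaluationReport:
    """Score predictions: overall error rate plus FPR/FNR for the positive class."""
    p = np.asarray(predictions, dtype=np.int64)
    y = np.asarray(true_labels, dtype=np.int64)
    if p.shape != y.shape or p.ndim != 1:
        raise ValidationError(f"predictions {p.shape} and labels {y.shape} must be equal-length vectors")
    n = p.size
    if n == 0:
        raise ValidationError("nothing to evaluate: empty prediction vector")
    err = float(np.count_nonzero(p != y)) / n
    pos = y == positive_class
    n_pos = int(pos.sum())
    n_neg = n - n_pos
    fp = int(np.count_nonzero((p == positive_class) & ~pos))
    fn = int(np.count_nonzero((p != positive_class) & pos))
    fpr = fp / n_neg if n_neg > 0 else float("nan")
    fnr = fn / n_pos if n_pos > 0 else float("nan")
    return EvaluationReport(error_rate=err, fpr=fpr, fnr=fnr, n_evaluated=n)


def rank_likelihoods(C: ConfusionMatrix) -> np.ndarray:
    """Row-normalized confusion counts: ``p(ranked k-th | true class j) = n_jk / n_j.``.

    Every row must have a positive marginal; the offending class index is
    reported otherwise.  Rows of the result sum to 1.
    """
    counts = C.counts
    marg = counts.sum(axis=1)
    zero = np.flatnonzero(marg == 0)
    if zero.size:
        raise ValidationError(f"zero row marginal for true class index {int(zero[0])}")
    return counts / marg[:, None]


def pairwise_independence_gap(
    decisions_a: Sequence[int], decisions_b: Sequence[int]
) -> float:
    """Largest deviation of the empirical joint from the product of marginals.

    ``max_{j,l} |p(a=j, b=l) - p(a=j) p(b=l)|`` over the observed decision
    pairs of two classifiers.  0 indicates exact empirical factorization;
    identical non-degenerate streams give a strictly positive gap — useful
    rankers are never independent in this unconditional sense.
    """
    a = np.asarray(decisions_a, dtype=np.int64)
    b = np.asarray(decisions_b, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValidationError("decision streams must be equal-length non-empty vectors")
    n = a.size
    vals_a = np.unique(a)
    vals_b = np.unique(b)
    gap = 0.0
    for j in vals_a:
        pa = np.count_nonzero(a == j) / n
        for l in vals_b:
            pb = np.count_nonzero(b == l) / n
            pj = np.count_nonzero((a == j) & (b == l)) / n
            gap = max(gap, abs(pj - pa * pb))
    return gap


def binary_marginal_decision_probability(alpha: float, prior: float = 0.5) -> float:
    """Marginal probability a symmetric binary classifier outputs class 1.

    For a two-class problem with ``p(correct) = alpha`` symmetric across
    classes and ``p(class 1) = prior``, the total probability rule gives
    ``alpha * prior + (1 - alpha) * (1 - prior)``.  With equiprobable classes
    this is 1/2 for every alpha — the observation that renders unconditional
    independence useless as a design criterion for accurate classifiers.
    """
    if not 0.0 <= alpha <= 1.0 or not 0.0 <= prior <= 1.0:
        raise ValidationError("alpha and prior must lie in [0, 1]")
    return alpha * prior + (1.0 - alpha) * (1.0 - prior)
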