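"""Small built-in example inputs.

The digit example is a published worked case of rank-classifier combination:
four classifiers each rank the ten handwritten digits 0-9 as candidate
identities of one test image (rank 1 = most likely).  It is small enough to
inspect by hand yet rich enough to exercise both consensus metrics — their
optimal rankings differ, and one digit pair is majority-tied under the
pairwise tally, so the deterministic tie-break is visible.
"""

from __future__ import annotations

import numpy as np

from .core import RankMatrix

__all__ = ["digit_ranking_example"]

# rows: digits 0-9; columns: classifiers K1-K4; entries: 1-based ranks
_DIGIT_RANKS = np.array(
    [
        [1, 4, 3, 10],
        [2, 2, 1, 2],
        [3, 1, 2, 1],
        [4, 6, 4, 3],
        [5, 5, 7, 5],
        [6, 3, 6, 4],
        [7, 8, 5, 6],
        [8, 7, 8, 9],
        [9, 10, 10, 8],
        [10, 9, 9, 7],
    ],
    dtype=np.int64,
)


def digit_ranking_example() -> RankMatrix:
    """Four classifiers' rankings of the digits 0-9 for one handwritten-digit image."""
    return RankMatrix(
        _DIGIT_RANKS.copy(),
        class_labels=tuple(str(d) for d in range(10)),
        classifier_labels=("K1", "K2", "K3", "K4"),
    )
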