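import numpy as np
import pytest

from rankfuse import RankMatrix, digit_ranking_example


@pytest.fixture(scope="session")
def digit_example() -> RankMatrix:
    """Four classifiers ranking the digits 0-9 (the built-in worked example)."""
    return digit_ranking_example()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_rank_matrix(rng: np.random.Generator, K: int, M: int) -> RankMatrix:
    cols = [rng.permutation(K) + 1 for _ in range(M)]
    return RankMatrix(np.column_stack(cols))
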