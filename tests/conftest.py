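import numpy as np
import pytest

from extsim import BinaryFingerprintSet

# The canonical worked pair: a=2, b=2, c=1, d=3.
PAIR_A = [1, 0, 1, 1, 0, 1, 0, 0]
PAIR_B = [0, 0, 1, 0, 0, 1, 0, 1]

# Four 4-bit fingerprints with column sums 4, 3, 2, 1.
QUAD = np.array(
    [
        [1, 1, 0, 0],
        [1, 0, 1, 0],
        [1, 1, 0, 1],
        [1, 1, 1, 0],
    ],
    dtype=np.uint8,
)


@pytest.fixture
def worked_pair() -> BinaryFingerprintSet:
    return BinaryFingerprintSet(np.array([PAIR_A, PAIR_B], dtype=np.uint8))


@pytest.fixture
def quad_set() -> BinaryFingerprintSet:
    return BinaryFingerprintSet(QUAD)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_set(rng: np.random.Generator, n: int, m: int, p: float = 0.5) -> BinaryFingerprintSet:
    return BinaryFingerprintSet((rng.random((n, m)) < p).astype(np.uint8))
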