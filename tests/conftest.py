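import numpy as np
import pytest

from rhsgibbs.coding import RawGenotypes


def random_raw(m: int, n: int, seed: int = 0) -> RawGenotypes:
    """Random polymorphic genotype matrix (resampled columns if monomorphic)."""
    rng = np.random.default_rng(seed)
    matrix = rng.integers(0, 3, size=(m, n)).astype(np.int8)
    for j in range(n):
        while len(np.unique(matrix[:, j])) == 1 or not (0 < matrix[:, j].mean() / 2 < 1):
            matrix[:, j] = rng.integers(0, 3, size=m)
    return RawGenotypes(matrix)


@pytest.fixture
def small_raw() -> RawGenotypes:
    return random_raw(12, 6, seed=7)
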