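import numpy as np
import pytest

from phenolearn import ExperimentSpace, PhenotypeMatrix


def matrix(rows, m=None, unobserved=0):
    """Build a PhenotypeMatrix from a list of lists (0 = unobserved)."""
    arr = np.asarray(rows, dtype=np.int32)
    m = m if m is not None else max(int(arr.max()), 1)
    space = ExperimentSpace.default(arr.shape[0], arr.shape[1], m)
    return PhenotypeMatrix(space, arr)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_sigma(rng, n_t, n_c, m, density):
    """Random partial observation matrix with at least one observation."""
    arr = rng.integers(1, m + 1, size=(n_t, n_c)).astype(np.int32)
    mask = rng.random((n_t, n_c)) < density
    if not mask.any():
        mask[rng.integers(n_t), rng.integers(n_c)] = True
    arr[~mask] = 0
    space = ExperimentSpace.default(n_t, n_c, m)
    return PhenotypeMatrix(space, arr)
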