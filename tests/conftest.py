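import numpy as np
import pytest

from nirtrace.spectra import SpectrumSet, WavenumberGrid


def make_set(matrix, grid=None, labels=None, prefix="s"):
    """Build a SpectrumSet around a raw matrix with sensible defaults."""
    a = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, p = a.shape
    if grid is None:
        grid = WavenumberGrid(np.linspace(9000.0, 5000.0, p))
    if labels is None:
        labels = ["A" if i % 2 == 0 else "B" for i in range(n)]
    ids = np.array([f"{prefix}{i}" for i in range(n)], dtype=object)
    return SpectrumSet(grid, a, np.array(labels, dtype=object), ids)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_set(rng):
    """10 random spectra on a 50-point descending grid, two classes."""
    return make_set(rng.normal(size=(10, 50)) + 2.0)


@pytest.fixture
def grid200():
    return WavenumberGrid.default(200)
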