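import numpy as np
import pytest

from bbpcarbon import BivariateDataset


@pytest.fixture
def worked_dataset() -> BivariateDataset:
    """Five-point dataset with Sxx = Syy = 10 and Sxy = 9 (r = 0.9)."""
    return BivariateDataset([1, 2, 3, 4, 5], [2, 3, 5, 4, 6])


@pytest.fixture
def exact_line() -> BivariateDataset:
    """Noise-free y = 2x + 1."""
    x = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
    return BivariateDataset(x, 2.0 * x + 1.0)


def random_dataset(rng: np.random.Generator, n: int | None = None) -> BivariateDataset:
    """A random correlated dataset for property tests."""
    if n is None:
        n = int(rng.integers(5, 51))
    x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3), size=n)
    slope = rng.uniform(-4, 4)
    y = slope * x + rng.uniform(-10, 10) + rng.normal(0, rng.uniform(0.1, 2), size=n)
    return BivariateDataset(x, y)
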