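import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def gaussian_cloud_2d(rng):
    """Fixed 50-point standard bivariate Gaussian cloud."""
    return rng.standard_normal((50, 2))


@pytest.fixture
def small_cloud_2d():
    """Fixed 5-point 2-D cloud used across quadrature/MC comparisons."""
    return np.array(
        [[0.3, -1.2], [1.5, 0.4], [-0.7, 0.9], [2.1, -0.3], [-1.1, -0.8]]
    )


@pytest.fixture
def three_cluster_cloud():
    """Three well-separated Gaussian clusters (no outliers)."""
    from yamm import cluster_fixture

    return cluster_fixture(
        [((0.0, 0.0), 0.4, 40), ((9.0, 1.0), 0.4, 40), ((3.0, 6.0), 0.4, 40)],
        seed=7,
    )
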