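import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def natural_table():
    from sibcut import natural_descriptor_table

    return natural_descriptor_table()


@pytest.fixture(scope="session")
def small_benchmark():
    """300 natural 21-mers with a strong sparse planted signal."""
    from sibcut import huesken_shaped_benchmark

    return huesken_shaped_benchmark(seed=11, n=300)


@pytest.fixture(scope="session")
def blob_data():
    """Two far-separated Gaussian blobs of 50 samples each."""
    rng = np.random.default_rng(7)
    a = rng.normal(loc=5.0, scale=1.0, size=(50, 10))
    b = rng.normal(loc=-5.0, scale=1.0, size=(50, 10))
    X = np.vstack([a, b])
    labels = np.array([0] * 50 + [1] * 50)
    return X, labels
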