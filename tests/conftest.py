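import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def flame_reference():
    from berrymetrics import load_flame_reference

    return load_flame_reference()


@pytest.fixture(scope="session")
def flame_estimates():
    from berrymetrics import load_flame_estimates

    return load_flame_estimates()


@pytest.fixture(scope="session")
def flame_pairs():
    """(estimated, reference) count arrays for the 30 packaged views."""
    from berrymetrics import paired_counts

    return paired_counts()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240101)
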