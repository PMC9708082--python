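import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from spikemux.models import QuadConfig  # noqa: E402
from spikemux.screen import Triplet  # noqa: E402

#: light quadrature for unit tests (accuracy still ~1e-3 in log units)
TEST_QUAD = QuadConfig(n_draws=2048, n_alpha=101, chunk=512, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def quad():
    return TEST_QUAD


@pytest.fixture
def mixture_triplet(rng):
    """A well-separated triplet whose AB counts are a 50/50 rate mixture."""
    return Triplet(
        "u0", "c0",
        rng.poisson(20, 20), rng.poisson(5, 20),
        np.where(rng.random(20) < 0.5, rng.poisson(20, 20), rng.poisson(5, 20)))
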