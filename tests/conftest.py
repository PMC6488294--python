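import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from empathynorms.norms import GameParams

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    # fixtures used inside @given are immutable parameter bundles; safe to share
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture
def standard_params() -> GameParams:
    """The standard parameter set: c=1, b=5, e1=e2=0.02."""
    return GameParams(b=5.0, c=1.0, e1=0.02, e2=0.02)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
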