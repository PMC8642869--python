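import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from pescreen import MaternalProfile, default_parameters


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture
def reference_profile():
    """Profile at the continuous-covariate centers with no risk factors,
    so every configured prior effect is zero under the default parameters."""
    return MaternalProfile(age=31.0, weight=63.1, height=159.5)
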