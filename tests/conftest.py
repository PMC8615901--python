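import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from munet.montage import build_montage

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def montage128():
    return build_montage(128)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
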