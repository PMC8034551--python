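import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def speckle_frame():
    """Small fully coherent speckle frame shared across tests."""
    from coherenet import SimConfig, generate_speckle_frame

    return generate_speckle_frame(SimConfig(n_axial=120, n_lines=16, seed=7))
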