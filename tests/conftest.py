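import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, database=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def snr100_scene():
    """A 100-particle sigma=1 SNR=100 benchmark scene, shared across tests."""
    import subpix as sp
    scene = sp.grid_scene(100, 1.0, snr=100, seed=1)
    img, truth = sp.simulate_scene(scene)
    return img, truth
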