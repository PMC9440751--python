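import numpy as np
import pytest
from hypothesis import settings

from morphoflight import simulate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rig():
    """Three orthogonal synthetic cameras around the flight volume."""
    return simulate.make_camera_rig()


@pytest.fixture(scope="session")
def default_flight():
    """One noiseless synthetic climbing flight with full truth."""
    return simulate.simulate_flight(simulate.FlightSimConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
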