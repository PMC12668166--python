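import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from helicrawl import RobotSpec, VesselProfile
from helicrawl.mechanics import default_mechanical_params

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def eb36():
    return RobotSpec(dr=3.6)


@pytest.fixture
def eb21():
    return RobotSpec(dr=2.1)


@pytest.fixture
def mech36(eb36):
    return default_mechanical_params(eb36)


def straight_vessel(d_start, d_end, length=60.0, n=121, incline_deg=0.0):
    th = np.radians(incline_deg)
    s = np.linspace(0.0, length, n)
    pts = s[:, None] * np.array([np.cos(th), 0.0, np.sin(th)])
    radius = (d_start + (d_end - d_start) * s / length) / 2.0
    return VesselProfile(centerline=pts, radius=radius)


@pytest.fixture
def worked_example_vessel():
    """The reference tapered segment: lumen 3.2 mm narrowing to 2.3 mm."""
    return straight_vessel(3.2, 2.3)
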