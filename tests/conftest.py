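import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

import railpattern as rp


@pytest.fixture
def water():
    """The surface tension consistent with the worked pressure values."""
    return rp.get_fluid("water_numeric")


@pytest.fixture
def basic_device():
    """Single-lane reference device: D=600, h=100, H=300, w=1000, l=5000 μm."""
    return rp.make_basic_device(600, 100, 300, 1000, 5000)


@pytest.fixture
def single_interface_options():
    return rp.PressureModelOptions(hr_convention=rp.HRConvention.SINGLE_INTERFACE)
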