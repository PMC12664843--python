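import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ecpmg import PulseCalibration, build_schedule

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cal600():
    """600 MHz proton channel calibration (8.4 us 90-degree pulse)."""
    return PulseCalibration(tau90=8.4e-6, larmor_mhz=600.0)


@pytest.fixture(scope="session")
def cal800():
    """800 MHz proton channel calibration (7.6 us 90-degree pulse)."""
    return PulseCalibration(tau90=7.6e-6, larmor_mhz=800.0)


@pytest.fixture(scope="session")
def sched600(cal600):
    """A 12-point schedule spanning 200 Hz - 30 kHz at 40 ms constant time."""
    return build_schedule(
        np.geomspace(200.0, 30000.0, 12), 0.040, cal600, divisor=4
    )
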