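import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from impactkin import ArrayGeometry, G, ImgSpec, ImpactSpec, NoiseSpec, TimeSeries3

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_ts(data, rate=1000.0, units="m/s^2", frame="head_ISO", start_time=0.0):
    return TimeSeries3(np.asarray(data, dtype=float), rate=rate, units=units,
                       frame=frame, start_time=start_time)


@pytest.fixture
def img_spec():
    return ImgSpec()


@pytest.fixture
def geom():
    return ArrayGeometry()


@pytest.fixture
def reference_impact():
    """A mid-range helmeted-drop impact: 100 g, 25 rad/s, 15 ms, front."""
    return ImpactSpec(
        location="front", speed=5.0, duration=0.015,
        lin_peak=100.0 * G, rot_vel_peak=25.0, seed=42,
    )


@pytest.fixture
def no_noise():
    return NoiseSpec.none()
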