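import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import physfix as pf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def protocol_small() -> pf.LoadProtocol:
    """Four cycles at the bench rate: enough to analyse cycles 2 and 3."""
    return pf.LoadProtocol(n_cycles=4)


@pytest.fixture
def params_default() -> pf.ConstructParams:
    return pf.ConstructParams(stiffness_true=1.10, toggle_true=5.08)


@pytest.fixture
def noise_free() -> pf.ConstructParams:
    return pf.ConstructParams(stiffness_true=1.10, toggle_true=5.08, angle_noise_sd=0.0)


def make_trace(angle, sample_rate: float = 1000.0, frequency: float = 0.5) -> pf.TorsionTrace:
    """Toy trace with a prescribed angle channel and sine torque."""
    angle = np.asarray(angle, dtype=float)
    n = len(angle)
    time = np.arange(n) / sample_rate
    torque = 2.0 * np.sin(2 * np.pi * frequency * time)
    n_cycles = max(int(n * frequency / sample_rate), 1)
    proto = pf.LoadProtocol(n_cycles=n_cycles, sample_rate=sample_rate, frequency=frequency)
    return pf.TorsionTrace(time=time, torque=torque, angle=angle, protocol=proto)
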