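import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import characean_ap as ca

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ap_av() -> ca.ParameterSet:
    """Average freshwater fit column (Hill n = 1)."""
    return ca.load_parameter_set(2, "AP_av Nitellopsis APW")


@pytest.fixture(scope="session")
def chara() -> ca.ParameterSet:
    """Reference Chara fit column (Hill n = 2)."""
    return ca.load_parameter_set(2, "AP_av Chara APW")


@pytest.fixture(scope="session")
def ap_av_result(ap_av) -> ca.APResult:
    """One 20 s simulation of the average AP with a 1 s pre-roll, shared
    across tests (read-only)."""
    return ca.simulate_ap(ap_av, t_end=20.0, dt_out=0.01, t_pre=1.0)


@pytest.fixture()
def triangle_trace() -> ca.Trace:
    """Symmetric triangular 'AP': 0 -> 100 -> 0 mV over 0-2-4 s, then flat."""
    t = np.arange(0.0, 6.0 + 1e-12, 0.01)
    v = np.where(t <= 2.0, 50.0 * t, np.where(t <= 4.0, 100.0 - 50.0 * (t - 2.0), 0.0))
    return ca.Trace(t, v)
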