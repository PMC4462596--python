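import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import clocknad as cn

settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def current():
    return cn.load_fixture("current")


@pytest.fixture(scope="session")
def hong2009():
    return cn.load_fixture("hong2009")


@pytest.fixture(scope="session")
def current_traj(current):
    """Free-running 20-day trajectory of the full model (shared)."""
    return cn.integrate(current.initial_state, current.parameters, t_end=480.0)


def series_after(traj, name, t0=120.0):
    mask = traj.times >= t0
    return traj.times[mask], traj.series(name)[mask]
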