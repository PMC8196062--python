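import numpy as np
import pytest
from hypothesis import settings

from discnav.kinematics import Trajectory

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20160501)


def make_trajectory(x, y, deployment_id="test", t=None, arena_radius_cm=10.0,
                    acclimation_s=0.0):
    x = np.asarray(x, dtype=float)
    if t is None:
        t = np.arange(x.size, dtype=float)
    return Trajectory(
        deployment_id=deployment_id,
        t=np.asarray(t, dtype=float),
        x=x,
        y=np.asarray(y, dtype=float),
        arena_radius_cm=arena_radius_cm,
        acclimation_s=acclimation_s,
    )


@pytest.fixture
def trajectory_factory():
    return make_trajectory
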