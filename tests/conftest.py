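import numpy as np
import pytest

from gaitrl.environment import SyntheticWalker, generate_reference_imu
from gaitrl.rewards import BodyKinematics, RewardWeights


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def walker():
    return SyntheticWalker()


@pytest.fixture
def reference_trace():
    return generate_reference_imu(duration=5.0, dt=0.01, seed=7)


def make_kinematics(
    v_body=(1.0, 0.0),
    v_tgt=(1.25, 0.0),
    activations=None,
    in_step=True,
    fallen=False,
    dt=0.01,
    r_left=(0.1, 0.12, 0.0),
    r_right=(-0.1, -0.12, 0.0),
    r_head=(0.0, 0.0, 1.5),
    r_pelvis=(0.0, 0.0, 0.92),
):
    """Hand-constructed kinematic summary for reward-term tests."""
    if activations is None:
        activations = np.full(6, 0.5)
    v_body = np.asarray(v_body, dtype=float)
    return BodyKinematics(
        v_body=v_body,
        v_vel=v_body.copy(),
        v_tgt=np.asarray(v_tgt, dtype=float),
        r_head=np.asarray(r_head, dtype=float),
        r_pelvis=np.asarray(r_pelvis, dtype=float),
        r_left=np.asarray(r_left, dtype=float),
        r_right=np.asarray(r_right, dtype=float),
        activations=np.asarray(activations, dtype=float),
        in_step=in_step,
        dt=dt,
        fallen=fallen,
    )


@pytest.fixture
def kin_factory():
    return make_kinematics


@pytest.fixture
def unit_weights():
    return RewardWeights()


@pytest.fixture
def baseline_weights():
    return RewardWeights.baseline()
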