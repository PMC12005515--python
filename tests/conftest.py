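import numpy as np
import pytest

from whiskenc.kinematics import decompose
from whiskenc.synth import KinematicsSpec, bin_ground_truth, generate_kinematics


@pytest.fixture(scope="session")
def kin_session():
    """One 300-s default synthetic session shared across tests."""
    return generate_kinematics(KinematicsSpec(duration=300.0, seed=12345))


@pytest.fixture(scope="session")
def kin_decomp(kin_session):
    return decompose(kin_session.angle, kin_session.angle_rate)


@pytest.fixture(scope="session")
def binned50(kin_session):
    """Ground-truth features of the shared session at 50-ms bins."""
    return bin_ground_truth(kin_session, 0.050)


@pytest.fixture(scope="session")
def binned25(kin_session):
    return bin_ground_truth(kin_session, 0.025)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def sinusoid(freq=10.0, rate=500.0, duration=4.0, mean=10.0, amp=5.0):
    t = np.arange(int(duration * rate)) / rate
    return mean + amp * np.sin(2 * np.pi * freq * t), rate
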