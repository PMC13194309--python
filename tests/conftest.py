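import numpy as np
import pytest

from suturesegkit.types import HandJointTrack, LabelSequence, RigidPoseTrack


def random_unit_quats(rng, n):
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_tool_track(rng):
    """A fully detected 30-frame track with smooth rotations."""
    T = 30
    angles = np.linspace(0.0, 0.8, T)
    quat = np.stack([np.cos(angles / 2), np.sin(angles / 2),
                     np.zeros(T), np.zeros(T)], axis=1)
    pos = np.stack([np.linspace(0, 1, T), np.zeros(T), np.ones(T)], axis=1)
    return RigidPoseTrack(pos, quat, np.ones(T, dtype=bool), "driver")


@pytest.fixture
def simple_hand_track(rng):
    T = 20
    joints = rng.normal(size=(T, 2, 21, 3))
    return HandJointTrack(joints, np.ones((T, 2), dtype=bool))


def make_labels(ids, fps=30.0):
    return LabelSequence(np.asarray(ids, dtype=np.int64), fps=fps)
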