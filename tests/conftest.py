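import numpy as np
import pytest

from kinassess.skeleton import JOINT_INDEX, JOINTS, SkeletonSequence
from kinassess.synthetic import ImpairmentProfile, simulate_trial


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_sequence(positions_by_joint, n_frames=2, fs=30.0, side="right", movement="RCH"):
    """Sequence with constant joint positions, defaulting to a neutral seated pose.

    ``positions_by_joint`` overrides individual joints (name -> 3-vector).
    """
    default_pose = {
        "spine_base": (0.0, 0.0, 0.0),
        "spine_mid": (0.0, 0.25, 0.0),
        "spine_shoulder": (0.0, 0.5, 0.0),
        "head": (0.0, 0.65, 0.0),
        "shoulder_L": (0.0, 0.5, -0.18),
        "shoulder_R": (0.0, 0.5, 0.18),
        "elbow_L": (0.0, 0.2, -0.18),
        "elbow_R": (0.0, 0.2, 0.18),
        "wrist_L": (0.25, 0.2, -0.18),
        "wrist_R": (0.25, 0.2, 0.18),
        "hand_L": (0.33, 0.2, -0.18),
        "hand_R": (0.33, 0.2, 0.18),
    }
    default_pose.update(positions_by_joint)
    positions = np.empty((n_frames, len(JOINTS), 3))
    for name, pos in default_pose.items():
        positions[:, JOINT_INDEX[name], :] = np.asarray(pos, dtype=float)
    t = np.arange(n_frames) / fs
    return SkeletonSequence(
        t=t, positions=positions, fs=fs, side=side, movement=movement, subject_id="test"
    )


def static_trial(fs=30.0, movement="RCH", duration=2.0):
    """Noiseless trial in which nothing moves (all excursions zero)."""
    profile = ImpairmentProfile(
        movement=movement, rom_sf=0.0, rom_sa=0.0, rom_ef=0.0, rom_wf=0.0,
        duration=duration, fs=fs,
    )
    return simulate_trial(profile, seed=0)
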