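import numpy as np
import pytest

from kinassess.errors import (
    DegenerateMovementError,
    ParameterError,
    ValidationError,
)
from kinassess.kinematics import (
    displacement_series,
    joint_angles,
    limb_length,
    normalized_jerk,
    rom,
)
from kinassess.segmentation import MovementPhase
from kinassess.synthetic import min_jerk_profile

from conftest import make_sequence


def angles_for(overrides, side="right"):
    return joint_angles(make_sequence(overrides, side=side))


class TestJointAngles:
    def test_shoulder_flexion_axis_aligned(self):
        down = angles_for({"shoulder_R": (0, 1.2, 0.2), "elbow_R": (0, 0.9, 0.2),
                           "wrist_R": (0.25, 0.9, 0.2)})
        assert down.SF[0] == pytest.approx(0.0, abs=1e-6)
        forward = angles_for({"shoulder_R": (0, 1.2, 0.2), "elbow_R": (0.3, 1.2, 0.2),
                              "wrist_R": (0.55, 1.2, 0.2)})
        assert forward.SF[0] == pytest.approx(90.0, abs=1e-6)

    def test_shoulder_adduction_axis_aligned(self):
        lateral = angles_for({"shoulder_R": (0, 1.2, 0.2), "elbow_R": (0, 1.2, 0.5),
                              "wrist_R": (0.25, 1.2, 0.5)})
        assert lateral.SA[0] == pytest.approx(0.0, abs=1e-6)
        down = angles_for({"shoulder_R": (0, 1.2, 0.2), "elbow_R": (0, 0.9, 0.2),
                           "wrist_R": (0.25, 0.9, 0.2)})
        assert down.SA[0] == pytest.approx(90.0, abs=1e-6)

    def test_elbow_flexion_straight_and_bent(self):
        straight = angles_for({"shoulder_R": (0, 1.2, 0.2), "elbow_R": (0, 0.9, 0.2),
                               "wrist_R": (0, 0.65, 0.2)})
        assert straight.EF[0] == pytest.approx(0.0, abs=1e-6)
        bent = angles_for({"shoulder_R": (0, 1.2, 0.2), "elbow_R": (0, 0.9, 0.2),
                           "wrist_R": (0.25, 0.9, 0.2)})
        assert bent.EF[0] == pytest.approx(90.0, abs=1e-6)

    def test_trunk_tilt_in_plane_cases(self):
        s10, c10 = np.sin(np.radians(10)), np.cos(np.radians(10))
        sagittal = angles_for({"spine_base": (0, 0, 0),
                               "spine_shoulder": (0.5 * s10, 0.5 * c10, 0)})
        assert sagittal.TF[0] == pytest.approx(10.0, abs=1e-6)
        assert sagittal.TL[0] == pytest.approx(0.0, abs=1e-6)
        assert sagittal.TT[0] == pytest.approx(90.0, abs=1e-6)
        s5, c5 = np.sin(np.radians(5)), np.cos(np.radians(5))
        frontal = angles_for({"spine_base": (0, 0, 0),
                              "spine_shoulder": (0, 0.5 * c5, 0.5 * s5)})
        assert frontal.TL[0] == pytest.approx(5.0, abs=1e-6)
        assert frontal.TF[0] == pytest.approx(0.0, abs=1e-6)
        assert frontal.TT[0] == pytest.approx(85.0, abs=1e-6)

    def test_wrist_flexion_dialects(self):
        # forearm forward, shoulder line right->left is -z: printed WF = 90 deg
        pose = {"elbow_R": (0, 0.9, 0.18), "wrist_R": (0.25, 0.9, 0.18),
                "hand_R": (0.25 + 0.08 * np.cos(np.radians(30)),
                           0.9 + 0.08 * np.sin(np.radians(30)), 0.18)}
        printed = joint_angles(make_sequence(pose), wf_formula="printed")
        assert printed.WF[0] == pytest.approx(90.0, abs=1e-6)
        hand = joint_angles(make_sequence(pose), wf_formula="hand_segment")
        assert hand.WF[0] == pytest.approx(30.0, abs=1e-6)

    def test_all_angles_within_bounds_on_random_frames(self, rng):
        from kinassess.errors import DegenerateGeometryError
        from kinassess.skeleton import JOINTS

        for _ in range(100):
            pose = {j: rng.normal(scale=0.4, size=3) for j in JOINTS}
            try:
                ang = joint_angles(make_sequence(pose))
            except DegenerateGeometryError:
                continue
            for name in ("SF", "SA", "EF", "WF", "TT", "TF", "TL"):
                vals = ang[name]
                assert np.all(vals >= 0.0) and np.all(vals <= 180.0)

    def test_invariance_to_translation_and_scale(self, rng):
        from kinassess.skeleton import JOINTS

        pose = {j: rng.normal(scale=0.4, size=3) + [0.0, 0.5, 0.0] for j in JOINTS}
        seq = make_sequence(pose)
        base = joint_angles(seq)
        shifted = seq.copy(positions=seq.positions + np.array([1.0, -2.0, 0.5]))
        scaled = seq.copy(positions=3.0 * (seq.positions - 0.2) + 0.2)
        for other in (joint_angles(shifted), joint_angles(scaled)):
            for name in ("SF", "SA", "EF", "WF", "TT", "TF", "TL"):
                np.testing.assert_allclose(other[name], base[name], atol=1e-9)

    def test_side_symmetry_on_mirrored_motion(self):
        from kinassess.synthetic import ImpairmentProfile, simulate_trial

        profile = ImpairmentProfile(movement="RCH", rom_sf=60, rom_sa=25, rom_ef=30,
                                    rom_wf=15, tt=5, tl=2, tf=3)
        right = joint_angles(simulate_trial(profile, seed=0, side="right"))
        left = joint_angles(simulate_trial(profile, seed=0, side="left"))
        for name in ("SF", "SA", "EF", "TT", "TF", "TL"):
            np.testing.assert_allclose(left[name], right[name], atol=1e-9)


class TestDisplacement:
    def test_static_joint_all_zeros(self):
        seq = make_sequence({}, n_frames=20)
        ds = displacement_series(seq, "head", "x", MovementPhase(2, 15), L=0.5)
        np.testing.assert_allclose(ds.values, 0.0, atol=1e-12)

    def test_hand_computed_head_forward(self):
        seq = make_sequence({}, n_frames=10)
        seq.positions[:, 0, 0] = np.linspace(0.0, 0.05, 10)  # head is joint 0
        ds = displacement_series(seq, "head", "x", MovementPhase(0, 9), L=0.5)
        assert ds.values[0] == 0.0
        assert ds.values[-1] == pytest.approx(0.10, abs=1e-12)

    def test_matches_brute_force(self, rng):
        seq = make_sequence({}, n_frames=30)
        seq.positions[:, 8, 1] = rng.normal(size=30)  # wrist_L vertical
        phase = MovementPhase(5, 25)
        ds = displacement_series(seq, "wrist_L", "y", phase, L=0.61)
        expect = [
            (seq.positions[i, 8, 1] - seq.positions[5, 8, 1]) / 0.61
            for i in range(5, 26)
        ]
        np.testing.assert_allclose(ds.values, expect, atol=1e-12)

    def test_invalid_limb_length_rejected(self):
        seq = make_sequence({}, n_frames=10)
        with pytest.raises(ParameterError):
            displacement_series(seq, "head", "x", MovementPhase(0, 9), L=0.0)


class TestLimbLength:
    def test_rigid_arm(self):
        seq = make_sequence({"shoulder_R": (0, 0.5, 0.18), "elbow_R": (0, 0.2, 0.18),
                             "wrist_R": (0.25, 0.2, 0.18)}, n_frames=5)
        assert limb_length(seq) == pytest.approx(0.55, abs=1e-12)

    def test_noisy_segments_average(self, rng):
        seq = make_sequence({}, n_frames=200)
        noise = rng.normal(0, 0.005, size=200)
        seq.positions[:, 7, 1] = 0.2 - noise  # elbow_R wobbles vertically
        value = limb_length(seq)
        assert abs(value - 0.55) < 0.01

    def test_zero_length_forearm_rejected(self):
        from kinassess.errors import DegenerateGeometryError

        seq = make_sequence({"wrist_R": (0.0, 0.2, 0.18)}, n_frames=3)
        with pytest.raises(DegenerateGeometryError):
            limb_length(seq)


class TestRom:
    def test_basic_cases(self):
        assert rom(np.full(10, 4.2), MovementPhase(0, 9)) == 0.0
        assert rom(np.array([0.0, 1.0, 3.0, 2.0]), MovementPhase(1, 3)) == 2.0

    def test_full_cycle_sinusoid(self):
        t = np.linspace(0, 1, 500)
        series = 3.5 * np.sin(2 * np.pi * t)
        assert rom(series, MovementPhase(0, 499)) == pytest.approx(7.0, abs=1e-4)

    def test_monotone_under_interval_inclusion(self, rng):
        series = rng.normal(size=100)
        inner = rom(series, MovementPhase(30, 60))
        outer = rom(series, MovementPhase(10, 80))
        assert outer >= inner

    def test_phase_outside_series_rejected(self):
        with pytest.raises(ValidationError):
            rom(np.zeros(10), MovementPhase(5, 20))


def straight_min_jerk_traj(T=1.0, fs=100.0, amplitude=0.3, direction=(1.0, 0.0, 0.0)):
    x = min_jerk_profile(0.0, amplitude, T, fs)
    return x[:, None] * np.asarray(direction)[None, :]


class TestNormalizedJerk:
    def test_closed_form_for_straight_minimum_jerk(self):
        traj = straight_min_jerk_traj()
        nj = normalized_jerk(traj, MovementPhase(0, len(traj) - 1), fs=100.0)
        assert nj == pytest.approx(np.sqrt(360.0), rel=0.02)

    def test_time_and_space_scale_invariance(self):
        fs = 100.0
        base = straight_min_jerk_traj(T=1.0, fs=fs)
        phase = MovementPhase(0, len(base) - 1)
        nj0 = normalized_jerk(base, phase, fs)
        # same samples replayed at half the rate = the movement time-scaled x2
        nj_t = normalized_jerk(base, phase, fs / 2.0)
        nj_s = normalized_jerk(3.0 * base, phase, fs)
        assert nj_t == pytest.approx(nj0, abs=1e-6)
        assert nj_s == pytest.approx(nj0, abs=1e-6)

    def test_minimum_among_perturbed_trajectories(self, rng):
        fs, T = 100.0, 1.0
        base = straight_min_jerk_traj(T=T, fs=fs)
        phase = MovementPhase(0, len(base) - 1)
        nj0 = normalized_jerk(base, phase, fs)
        t = np.arange(len(base)) / fs / T
        for _ in range(10):
            # smooth perturbation vanishing (with derivatives) at the endpoints
            k = rng.integers(2, 6)
            amp = rng.uniform(0.02, 0.05) * rng.choice([-1.0, 1.0])
            wiggle = amp * np.sin(np.pi * k * t) ** 3
            perturbed = base + wiggle[:, None] * np.array([1.0, 0.5, 0.0])
            assert normalized_jerk(perturbed, phase, fs) > nj0

    def test_static_trajectory_degenerate(self):
        traj = np.zeros((100, 3))
        with pytest.raises(DegenerateMovementError):
            normalized_jerk(traj, MovementPhase(0, 99), fs=100.0)
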