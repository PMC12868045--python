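import json

import numpy as np
import pytest

from kinassess.errors import DegenerateGeometryError, FormatError, ValidationError
from kinassess.skeleton import (
    JOINTS,
    SkeletonSequence,
    csv_columns,
    read_skeleton_csv,
    segment_vectors,
    to_body_frame,
    write_skeleton_csv,
)
from kinassess.synthetic import ImpairmentProfile, simulate_trial

from conftest import make_sequence


def _write_manifest(path, **overrides):
    meta = {"fs_hz": 30.0, "side": "right", "movement": "RCH", "subject_id": "s1",
            "fm_score": None}
    meta.update(overrides)
    path.write_text(json.dumps(meta))


def _two_frame_csv_text():
    header = ",".join(csv_columns())
    rows = []
    for i in range(2):
        vals = [f"{i / 30.0:.6f}"]
        for k, _ in enumerate(JOINTS):
            vals += [f"{0.1 * k}", f"{0.2 + 0.01 * i}", "0.0"]
        rows.append(",".join(vals))
    return header + "\n" + "\n".join(rows) + "\n"


class TestReadWrite:
    def test_two_frame_handwritten_csv(self, tmp_path):
        csv = tmp_path / "trial.csv"
        csv.write_text(_two_frame_csv_text())
        _write_manifest(tmp_path / "trial.json")
        seq = read_skeleton_csv(csv, tmp_path / "trial.json")
        assert seq.n_frames == 2
        assert seq.fs == 30.0
        assert seq.movement == "RCH"
        assert seq.joint("head")[0, 0] == 0.0
        assert seq.joint("spine_shoulder")[1, 1] == pytest.approx(0.21)

    def test_round_trip_identity(self, tmp_path):
        profile = ImpairmentProfile(movement="HTM", rom_sf=20, rom_sa=10, rom_ef=40,
                                    noise_sd=0.001)
        seq = simulate_trial(profile, seed=3, subject_id="rt", fm_score=40)
        path = write_skeleton_csv(seq, tmp_path / "rt.csv")
        back = read_skeleton_csv(path, path.with_suffix(".json"))
        np.testing.assert_allclose(back.positions, seq.positions, atol=1e-9)
        np.testing.assert_allclose(back.t, seq.t, atol=1e-9)
        assert (back.fs, back.side, back.movement) == (seq.fs, seq.side, seq.movement)
        assert back.subject_id == "rt" and back.fm_score == 40

    def test_missing_column_is_named(self, tmp_path):
        lines = _two_frame_csv_text().splitlines()
        cols = lines[0].split(",")
        drop = cols.index("head_z")
        trimmed = "\n".join(
            ",".join(v for i, v in enumerate(line.split(",")) if i != drop)
            for line in lines
        )
        csv = tmp_path / "bad.csv"
        csv.write_text(trimmed)
        _write_manifest(tmp_path / "bad.json")
        with pytest.raises(FormatError, match="head_z"):
            read_skeleton_csv(csv, tmp_path / "bad.json")

    def test_non_monotonic_time_rejected(self, tmp_path):
        text = _two_frame_csv_text().splitlines()
        text[2] = text[2].replace(f"{1 / 30.0:.6f}", "0.000000", 1)
        csv = tmp_path / "t.csv"
        csv.write_text("\n".join(text))
        _write_manifest(tmp_path / "t.json")
        with pytest.raises(ValidationError, match="increasing"):
            read_skeleton_csv(csv, tmp_path / "t.json")

    def test_unknown_movement_rejected(self, tmp_path):
        csv = tmp_path / "m.csv"
        csv.write_text(_two_frame_csv_text())
        _write_manifest(tmp_path / "m.json", movement="walk")
        with pytest.raises(ValidationError, match="walk"):
            read_skeleton_csv(csv, tmp_path / "m.json")

    def test_row_count_one_second_trial(self, tmp_path):
        fs = 30.0
        seq = make_sequence({}, n_frames=int(fs) + 1, fs=fs)
        path = write_skeleton_csv(seq, tmp_path / "one.csv")
        assert len(path.read_text().splitlines()) == int(fs) + 2  # header + rows

    def test_empty_sequence_not_written(self, tmp_path):
        seq = SkeletonSequence(
            t=np.array([]), positions=np.empty((0, 12, 3)), fs=30.0,
            side="right", movement="RCH", validate=False,
        )
        target = tmp_path / "empty.csv"
        with pytest.raises(ValidationError):
            write_skeleton_csv(seq, target)
        assert not target.exists()

    def test_calibration_block_applied_on_read(self, tmp_path):
        seq = make_sequence({}, n_frames=3)
        path = write_skeleton_csv(seq, tmp_path / "cal.csv")
        # rotate camera coords 90 deg about y: body x was camera -z
        rot = [0, 0, -1, 0, 1, 0, 1, 0, 0]
        meta = json.loads(path.with_suffix(".json").read_text())
        meta["calibration"] = {"rotation": rot, "origin": [0.0, 0.1, 0.0]}
        path.with_suffix(".json").write_text(json.dumps(meta))
        back = read_skeleton_csv(path, path.with_suffix(".json"))
        expected = np.einsum(
            "ij,nkj->nki", np.array(rot, float).reshape(3, 3),
            seq.positions - np.array([0.0, 0.1, 0.0]),
        )
        np.testing.assert_allclose(back.positions, expected, atol=1e-12)


class TestBodyFrame:
    def test_identity_is_noop(self):
        seq = make_sequence({}, n_frames=4)
        out = to_body_frame(seq, np.eye(3), np.zeros(3))
        np.testing.assert_allclose(out.positions, seq.positions, atol=1e-15)

    def test_rotation_composition(self):
        seq = make_sequence({}, n_frames=3)

        def roty(deg):
            a = np.radians(deg)
            return np.array([[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]])

        twice = to_body_frame(to_body_frame(seq, roty(90), np.zeros(3)), roty(90), np.zeros(3))
        once = to_body_frame(seq, roty(180), np.zeros(3))
        np.testing.assert_allclose(twice.positions, once.positions, atol=1e-12)

    def test_random_rotation_preserves_distances(self, rng):
        from scipy.spatial.transform import Rotation

        seq = make_sequence({}, n_frames=3)
        rot = Rotation.random(random_state=np.random.RandomState(7)).as_matrix()
        out = to_body_frame(seq, rot, rng.normal(size=3))
        for i in range(seq.n_frames):
            d_in = np.linalg.norm(
                seq.positions[i][:, None, :] - seq.positions[i][None, :, :], axis=2
            )
            d_out = np.linalg.norm(
                out.positions[i][:, None, :] - out.positions[i][None, :, :], axis=2
            )
            np.testing.assert_allclose(d_out, d_in, atol=1e-12)

    def test_non_orthonormal_matrix_rejected(self):
        seq = make_sequence({}, n_frames=2)
        with pytest.raises(ValidationError):
            to_body_frame(seq, np.eye(3) * 2.0, np.zeros(3))
        with pytest.raises(ValidationError):  # reflection: det = -1
            to_body_frame(seq, np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestSegmentVectors:
    def test_hand_computed_se(self):
        seq = make_sequence({"shoulder_R": (0, 1.2, 0.2), "elbow_R": (0, 0.9, 0.2)})
        sv = segment_vectors(seq.frame(0), "right")
        np.testing.assert_allclose(sv.SE, [0, -1, 0], atol=1e-12)

    def test_hand_computed_tr(self):
        seq = make_sequence({"spine_base": (0, 0.8, 0), "spine_shoulder": (0, 1.3, 0)})
        sv = segment_vectors(seq.frame(0), "right")
        np.testing.assert_allclose(sv.TR, [0, 1, 0], atol=1e-12)

    def test_sh_is_right_to_left_for_both_sides(self):
        seq = make_sequence({})
        for side in ("left", "right"):
            sv = segment_vectors(seq.frame(0), side)
            np.testing.assert_allclose(sv.SH, [0, 0, -1], atol=1e-12)
        assert segment_vectors(seq.frame(0), "left").u_z[2] == -1.0

    def test_coincident_joints_degenerate(self):
        seq = make_sequence({"wrist_R": (0.0, 0.2, 0.18), "elbow_R": (0.0, 0.2, 0.18)})
        with pytest.raises(DegenerateGeometryError, match="EW"):
            segment_vectors(seq.frame(0), "right")

    def test_all_outputs_unit_norm_on_random_frames(self, rng):
        for _ in range(50):
            jitter = {j: rng.normal(scale=0.3, size=3) + [0.1, 0.5, 0.0] for j in JOINTS}
            seq = make_sequence(jitter)
            try:
                sv = segment_vectors(seq.frame(0), "right")
            except DegenerateGeometryError:
                continue
            for name in ("SE", "EW", "WH", "SH", "TR"):
                assert abs(np.linalg.norm(getattr(sv, name)) - 1.0) < 1e-9


def test_frame_spacing_validated():
    t = np.array([0.0, 0.1, 0.2])
    pos = np.zeros((3, 12, 3))
    with pytest.raises(ValidationError, match="spacing"):
        SkeletonSequence(t=t, positions=pos, fs=30.0, side="right", movement="RCH")
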