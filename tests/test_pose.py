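import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from suturesegkit import pose
from suturesegkit.types import (
    HandJointTrack,
    PreprocessConfig,
    RigidPoseTrack,
    ValidationError,
)


def smooth_rotation_quats(T, rng=None, step=0.05):
    """A slowly varying rotation path (small geodesic steps)."""
    if rng is None:
        rng = np.random.default_rng(0)
    rot = Rotation.identity()
    out = []
    for _ in range(T):
        rot = Rotation.from_rotvec(rng.normal(0, step, 3)) * rot
        out.append(pose.rotation_to_quat(rot))
    return np.stack(out)


def make_track(quats, detected=None):
    T = len(quats)
    if detected is None:
        detected = np.ones(T, dtype=bool)
    return RigidPoseTrack(np.zeros((T, 3)), quats, detected, "driver")


class TestDisambiguation:
    def test_consistent_track_unchanged(self):
        track = make_track(smooth_rotation_quats(20))
        out = pose.disambiguate_tool_rotations(track)
        np.testing.assert_allclose(out.rotations, track.rotations, atol=1e-12)

    def test_single_flipped_frame_corrected(self):
        q = pose.rotation_to_quat(Rotation.from_rotvec([0.3, 0.1, 0.2]))
        quats = np.tile(q, (10, 1))
        quats[5] = pose.quat_multiply(q, pose.RY_180_QUAT)
        out = pose.disambiguate_tool_rotations(make_track(quats))
        for t in range(10):
            assert pose.geodesic_angle(out.rotations[t], q) < 1e-9

    def test_greedy_matches_global_brute_force(self):
        """Greedy per-frame choice equals the minimum-total-path assignment
        found by brute force over all 2^T symmetry assignments (T=8)."""
        rng = np.random.default_rng(7)
        base = smooth_rotation_quats(8, rng, step=0.08)
        corrupt = base.copy()
        flips = rng.random(8) < 0.5
        for t in np.flatnonzero(flips):
            corrupt[t] = pose.quat_multiply(corrupt[t], pose.RY_180_QUAT)
        greedy = pose.disambiguate_tool_rotations(make_track(corrupt))

        def path_cost(quats):
            return sum(pose.geodesic_angle(quats[t - 1], quats[t])
                       for t in range(1, len(quats)))

        best_cost = np.inf
        syms = [pose.IDENTITY_QUAT, pose.RY_180_QUAT]
        for assign in itertools.product(range(2), repeat=7):
            quats = [corrupt[0]]  # first frame fixed, as in the greedy rule
            for t, a in enumerate(assign, start=1):
                quats.append(pose.quat_multiply(corrupt[t], syms[a]))
            best_cost = min(best_cost, path_cost(quats))
        assert path_cost(greedy.rotations) == pytest.approx(best_cost, abs=1e-9)

    def test_single_frame_unchanged(self):
        track = make_track(smooth_rotation_quats(1))
        out = pose.disambiguate_tool_rotations(track)
        np.testing.assert_array_equal(out.rotations, track.rotations)

    def test_output_is_input_times_symmetry(self):
        rng = np.random.default_rng(3)
        quats = smooth_rotation_quats(30, rng)
        flips = rng.random(30) < 0.3
        for t in np.flatnonzero(flips):
            quats[t] = pose.quat_multiply(quats[t], pose.RY_180_QUAT)
        out = pose.disambiguate_tool_rotations(make_track(quats))
        for t in range(30):
            angles = [pose.geodesic_angle(out.rotations[t],
                                          pose.quat_multiply(quats[t], s))
                      for s in pose.DEFAULT_SYMMETRY]
            assert min(angles) < 1e-6  # acos precision floor ~3e-8 rad

    def test_flip_recovery_up_to_global_symmetry(self):
        """Randomly flip-corrupted smooth tracks are recovered exactly up to
        one global symmetry element."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            base = smooth_rotation_quats(60, rng)
            corrupt = base.copy()
            for t in np.flatnonzero(rng.random(60) < 0.4):
                corrupt[t] = pose.quat_multiply(corrupt[t], pose.RY_180_QUAT)
            out = pose.disambiguate_tool_rotations(make_track(corrupt))
            residual = [max(pose.geodesic_angle(out.rotations[t],
                                                pose.quat_multiply(base[t], s))
                            for t in range(60))
                        for s in pose.DEFAULT_SYMMETRY]
            assert min(residual) < 1e-6

    def test_symmetry_set_validation(self, simple_tool_track):
        with pytest.raises(ValidationError, match="non-empty"):
            pose.disambiguate_tool_rotations(simple_tool_track, [])
        with pytest.raises(ValidationError, match="identity"):
            pose.disambiguate_tool_rotations(simple_tool_track,
                                             [pose.RY_180_QUAT])


class TestLocf:
    def _gappy(self, gap, lead=5):
        T = lead + gap + 5
        detected = np.ones(T, dtype=bool)
        detected[lead:lead + gap] = False
        quats = np.tile([1.0, 0, 0, 0], (T, 1))
        pos = np.arange(T, dtype=float)[:, None] * [1.0, 0, 0]
        return RigidPoseTrack(pos, quats, detected, "driver")

    def test_gap_of_ten_filled_eleven_not(self):
        filled = pose.impute_locf(self._gappy(10), max_gap_frames=10)
        assert filled.valid.all()
        assert np.all(filled.positions[5:15, 0] == 4.0)
        untouched = pose.impute_locf(self._gappy(11), max_gap_frames=10)
        assert not untouched.imputed.any()

    def test_fully_detected_identity(self, simple_tool_track):
        out = pose.impute_locf(simple_tool_track, 10)
        np.testing.assert_array_equal(out.positions, simple_tool_track.positions)
        assert not out.imputed.any()

    def test_leading_gap_untouched(self):
        tr = self._gappy(3, lead=0)
        out = pose.impute_locf(tr, 10)
        assert not out.imputed[:3].any()

    def test_detected_frames_never_modified(self):
        tr = self._gappy(4)
        out = pose.impute_locf(tr, 10)
        det = tr.detected
        np.testing.assert_array_equal(out.positions[det], tr.positions[det])


class TestLinearInterpolation:
    def test_closed_form_interior_gap(self):
        T = 4
        joints = np.zeros((T, 2, 21, 3))
        joints[3, :, :, 0] = 3.0
        detected = np.ones((T, 2), dtype=bool)
        detected[1:3, :] = False
        out = pose.interpolate_gaps_linear(HandJointTrack(joints, detected), 10)
        assert out.joints[1, 0, 0, 0] == pytest.approx(1.0)
        assert out.joints[2, 0, 0, 0] == pytest.approx(2.0)
        assert out.detected.all()

    def test_long_gap_untouched(self):
        T = 13
        joints = np.zeros((T, 2, 21, 3))
        detected = np.ones((T, 2), dtype=bool)
        detected[1:12, :] = False  # gap of 11
        out = pose.interpolate_gaps_linear(HandJointTrack(joints, detected), 10)
        assert not out.detected[1:12].any()

    def test_boundary_gaps_untouched(self):
        T = 6
        joints = np.zeros((T, 2, 21, 3))
        detected = np.ones((T, 2), dtype=bool)
        detected[:2, 0] = False
        detected[4:, 1] = False
        out = pose.interpolate_gaps_linear(HandJointTrack(joints, detected), 10)
        assert not out.detected[:2, 0].any() and not out.detected[4:, 1].any()

    def test_no_gaps_identity(self, simple_hand_track):
        out = pose.interpolate_gaps_linear(simple_hand_track, 10)
        np.testing.assert_array_equal(out.joints, simple_hand_track.joints)


class TestSavitzkyGolay:
    def test_constant_signal_unchanged(self, simple_tool_track):
        tr = simple_tool_track.copy()
        tr.positions[:] = [1.0, 2.0, 3.0]
        out = pose.smooth_savitzky_golay(tr)
        np.testing.assert_allclose(out.positions, tr.positions, atol=1e-12)

    def test_quadratic_reproduced_exactly(self):
        """Order-2 filtering is exact on quadratics, checked against an
        explicit per-window least-squares polynomial fit."""
        T = 40
        t = np.arange(T, dtype=float)
        quad = 0.3 * t ** 2 - 2.0 * t + 5.0
        pos = np.stack([quad, -quad, 0.5 * quad], axis=1)
        quats = np.tile([1.0, 0, 0, 0], (T, 1))
        tr = RigidPoseTrack(pos, quats, np.ones(T, dtype=bool), "x")
        cfg = PreprocessConfig(savgol_window=9, savgol_order=2)
        out = pose.smooth_savitzky_golay(tr, cfg)
        np.testing.assert_allclose(out.positions, pos, atol=1e-9)
        # independent oracle: centered least-squares quadratic fit per window
        w = 9
        for center in range(w // 2, T - w // 2):
            window = np.arange(center - w // 2, center + w // 2 + 1)
            coeffs = np.polyfit(window, quad[window], 2)
            assert np.polyval(coeffs, center) == pytest.approx(
                out.positions[center, 0], abs=1e-9)

    def test_noise_variance_reduced(self, rng):
        T = 200
        noise = rng.normal(size=(T, 3))
        quats = np.tile([1.0, 0, 0, 0], (T, 1))
        tr = RigidPoseTrack(noise, quats, np.ones(T, dtype=bool), "x")
        out = pose.smooth_savitzky_golay(tr)
        assert out.positions.var() < noise.var()

    def test_quaternions_stay_unit_norm(self):
        quats = smooth_rotation_quats(50)
        out = pose.smooth_savitzky_golay(make_track(quats))
        np.testing.assert_allclose(np.linalg.norm(out.rotations, axis=1), 1.0,
                                   atol=1e-12)

    def test_short_spans_passed_through(self):
        T = 5  # shorter than default window 9
        quats = np.tile([1.0, 0, 0, 0], (T, 1))
        pos = np.arange(15, dtype=float).reshape(5, 3)
        tr = RigidPoseTrack(pos, quats, np.ones(T, dtype=bool), "x")
        out = pose.smooth_savitzky_golay(tr)
        np.testing.assert_array_equal(out.positions, pos)

    def test_invalid_window_rejected(self, simple_tool_track):
        with pytest.raises(ValidationError):
            pose.smooth_savitzky_golay(simple_tool_track,
                                       PreprocessConfig(savgol_window=8))

    def test_missing_frames_not_used(self):
        """A wild outlier at an undetected frame must not leak into smoothing."""
        T = 30
        quats = np.tile([1.0, 0, 0, 0], (T, 1))
        pos = np.zeros((T, 3))
        pos[15] = 1e6
        detected = np.ones(T, dtype=bool)
        detected[15] = False
        tr = RigidPoseTrack(pos, quats, detected, "x")
        out = pose.smooth_savitzky_golay(tr)
        assert np.abs(out.positions[detected]).max() < 1.0


class TestAugmentation:
    def _find_seed(self, p, want):
        """Seed whose first two uniform draws compare to p as requested."""
        for seed in range(1000):
            r = np.random.default_rng(seed)
            draws = (r.random() < p, r.random() < p)
            if draws == want:
                return seed
        raise AssertionError("no such seed in range")

    def test_no_flips_no_noise_is_identity(self, simple_tool_track):
        cfg = PreprocessConfig(tool_noise_sigma=0.0, flip_probability=0.5)
        seed = self._find_seed(0.5, (False, False))
        out = pose.augment_tool_pose(simple_tool_track, cfg, seed)
        np.testing.assert_array_equal(out.positions, simple_tool_track.positions)
        np.testing.assert_array_equal(out.rotations, simple_tool_track.rotations)

    def test_y_flip_maps_positions(self, simple_tool_track):
        cfg = PreprocessConfig(tool_noise_sigma=0.0, flip_probability=0.5)
        seed = self._find_seed(0.5, (True, False))
        tr = simple_tool_track.copy()
        tr.positions[0] = [1.0, 2.0, 3.0]
        out = pose.augment_tool_pose(tr, cfg, seed)
        np.testing.assert_allclose(out.positions[0], [-1.0, 2.0, -3.0])

    def test_deterministic_given_seed(self, simple_tool_track):
        cfg = PreprocessConfig()
        a = pose.augment_tool_pose(simple_tool_track, cfg, seed=42)
        b = pose.augment_tool_pose(simple_tool_track, cfg, seed=42)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.rotations, b.rotations)

    def test_flips_preserve_relative_rotations(self, simple_tool_track):
        """Flips are rigid per video: inter-frame relative rotation unchanged."""
        cfg = PreprocessConfig(tool_noise_sigma=0.0, flip_probability=1.0)
        out = pose.augment_tool_pose(simple_tool_track, cfg, seed=0)
        for t in range(1, len(out)):
            before = pose.geodesic_angle(simple_tool_track.rotations[t - 1],
                                         simple_tool_track.rotations[t])
            after = pose.geodesic_angle(out.rotations[t - 1], out.rotations[t])
            assert after == pytest.approx(before, abs=1e-9)

    def test_hand_rotation_preserves_distances(self, simple_hand_track):
        out = pose.augment_hand_pose(simple_hand_track, seed=5)
        for f in (0, 7):
            orig = simple_hand_track.joints[f, 0]
            new = out.joints[f, 0]
            d0 = np.linalg.norm(orig[:, None] - orig[None, :], axis=-1)
            d1 = np.linalg.norm(new[:, None] - new[None, :], axis=-1)
            np.testing.assert_allclose(d1, d0, atol=1e-9)

    def test_hand_rotation_fixes_axis(self, simple_hand_track):
        tr = simple_hand_track.copy()
        tr.joints[0, 0, 0] = [0.0, 5.0, 0.0]  # on the default vertical axis
        out = pose.augment_hand_pose(tr, seed=5)
        np.testing.assert_allclose(out.joints[0, 0, 0], [0.0, 5.0, 0.0],
                                   atol=1e-9)

    def test_hand_deterministic(self, simple_hand_track):
        a = pose.augment_hand_pose(simple_hand_track, seed=9)
        b = pose.augment_hand_pose(simple_hand_track, seed=9)
        np.testing.assert_array_equal(a.joints, b.joints)


class TestTracksToFeatures:
    def test_two_tools_dim_16(self, simple_tool_track):
        other = simple_tool_track.copy()
        other.tool_id = "tweezers"
        feats = pose.tracks_to_features(
            tools={"driver": simple_tool_track, "tweezers": other})
        assert feats.dim == 16 and feats.modality == "tools"

    def test_hands_dim_128_with_126_coordinates(self, simple_hand_track):
        feats = pose.tracks_to_features(hands=simple_hand_track, modality="hands")
        assert feats.dim == 128
        np.testing.assert_allclose(feats.values[0, :126],
                                   simple_hand_track.joints[0].reshape(-1))
        assert feats.values[0, 126:].tolist() == [1.0, 1.0]

    def test_invalid_frames_zero_filled(self, simple_tool_track):
        tr = simple_tool_track.copy()
        tr.detected[4] = False
        feats = pose.tracks_to_features(tools={"driver": tr})
        assert feats.values[4].tolist() == [0.0] * 8

    def test_length_mismatch_rejected(self, simple_tool_track):
        short = RigidPoseTrack(np.zeros((3, 3)),
                               np.tile([1.0, 0, 0, 0], (3, 1)),
                               np.ones(3, dtype=bool), "tweezers")
        with pytest.raises(ValidationError, match="length"):
            pose.tracks_to_features(tools={"a": simple_tool_track, "b": short})
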