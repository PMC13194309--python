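"""Cleaning, imputation, smoothing and augmentation of pose tracks.

Tool tracks suffer from two estimator artifacts: symmetry flips (the tool is
rotationally symmetric, so the estimator may return a pose rotated by a
symmetry element, discontinuous in time) and dropped detections.  The
cleaning order is: flip disambiguation, then gap imputation (LOCF for tools,
linear interpolation for hands, both bounded at 10 frames), then
Savitzky-Golay smoothing.  Augmentations — whole-video 180-degree flips,
whole-video random rotation of hand joints, additive noise — are applied at
training time only.
"""
from __future__ import annotations

import math
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.signal import savgol_filter
from scipy.spatial.transform import Rotation

from .types import (
    FeatureSequence,
    HandJointTrack,
    PreprocessConfig,
    RigidPoseTrack,
    ValidationError,
)

# scalar-first (qw,qx,qy,qz) <-> scipy scalar-last (qx,qy,qz,qw)

def quat_to_rotation(q: np.ndarray) -> Rotation:
    q = np.asarray(q, dtype=np.float64)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))


def rotation_to_quat(r: Rotation) -> np.ndarray:
    return np.roll(r.as_quat(), 1, axis=-1)


IDENTITY_QUAT = np.array([1.0, 0.0, 0.0, 0.0])
RY_180_QUAT = np.array([0.0, 0.0, 1.0, 0.0])  # 180 deg about y

DEFAULT_SYMMETRY: tuple[np.ndarray, ...] = (IDENTITY_QUAT, RY_180_QUAT)


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product a*b for scalar-first quaternions."""
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return np.array([
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    ])


def geodesic_angle(qa: np.ndarray, qb: np.ndarray) -> float:
    """Geodesic angle in radians between two scalar-first unit quaternions."""
    d = abs(float(np.dot(qa, qb)))
    return 2.0 * math.acos(min(1.0, d))


def _runs(mask: np.ndarray):
    """Yield (start, end) of maximal True runs (half-open)."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        yield int(s), int(e)


# ---------------------------------------------------------------- flips

def disambiguate_tool_rotations(track: RigidPoseTrack,
                                symmetry: Optional[Sequence[np.ndarray]] = None,
                                ) -> RigidPoseTrack:
    """Resolve per-frame symmetry-flip ambiguity greedily in frame order.

    For each detected frame the symmetry element minimizing the geodesic
    angle to the previously corrected detected frame is applied on the
    right of the stored rotation.  The first detected frame is left
    unchanged, so recovery is up to one global symmetry element.
    """
    if symmetry is None:
        symmetry = DEFAULT_SYMMETRY
    symmetry = [np.asarray(s, dtype=np.float64) for s in symmetry]
    if not symmetry:
        raise ValidationError("symmetry set must be non-empty")
    if not any(np.allclose(s, IDENTITY_QUAT) or np.allclose(s, -IDENTITY_QUAT)
               for s in symmetry):
        raise ValidationError("symmetry set must contain the identity")
    out = track.copy()
    prev: Optional[np.ndarray] = None
    for t in np.flatnonzero(track.detected):
        q = out.rotations[t]
        if prev is None:
            prev = q
            continue
        best, best_angle = q, np.inf
        for s in symmetry:
            cand = quat_multiply(q, s)
            ang = geodesic_angle(prev, cand)
            if ang < best_angle:
                best, best_angle = cand, ang
        out.rotations[t] = best
        prev = best
    return out


# ---------------------------------------------------------------- imputation

def impute_locf(track: RigidPoseTrack, max_gap_frames: int = 10) -> RigidPoseTrack:
    """Last-observation-carried-forward over undetected gaps of bounded length.

    A maximal undetected run of length <= ``max_gap_frames`` immediately
    following a detected frame is filled with that frame's pose and flagged
    imputed; longer runs and leading runs stay missing.
    """
    if max_gap_frames < 0:
        raise ValidationError("max_gap_frames must be >= 0")
    out = track.copy()
    if not track.detected.any():
        return out
    for s, e in _runs(~track.detected):
        if s == 0 or (e - s) > max_gap_frames:
            continue
        out.positions[s:e] = track.positions[s - 1]
        out.rotations[s:e] = track.rotations[s - 1]
        out.imputed[s:e] = True
    return out


def interpolate_gaps_linear(track: HandJointTrack, max_gap_frames: int = 10
                            ) -> HandJointTrack:
    """Linear interpolation of interior per-hand gaps of bounded length.

    Requires a detected frame on both sides of the gap; boundary gaps stay
    missing.  Interpolated frames are flagged detected (they now carry data
    usable downstream).
    """
    if max_gap_frames < 0:
        raise ValidationError("max_gap_frames must be >= 0")
    out = track.copy()
    T = len(track)
    for h in range(2):
        det = track.detected[:, h]
        for s, e in _runs(~det):
            if s == 0 or e == T or (e - s) > max_gap_frames:
                continue
            a, b = track.joints[s - 1, h], track.joints[e, h]
            gap = e - s
            for i in range(gap):
                w = (i + 1) / (gap + 1)
                out.joints[s + i, h] = (1 - w) * a + w * b
            out.detected[s:e, h] = True
    return out


# ---------------------------------------------------------------- smoothing

def _savgol_span(x: np.ndarray, window: int, order: int) -> np.ndarray:
    return savgol_filter(x, window, order, axis=0, mode="interp")


def smooth_savitzky_golay(track, cfg: Optional[PreprocessConfig] = None):
    """Savitzky-Golay smoothing within contiguous observed spans.

    Positions and joint coordinates are filtered per coordinate; quaternions
    are made sign-continuous, filtered componentwise and renormalized.
    Missing frames are never used as filter inputs; spans shorter than the
    window pass through unchanged.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    w, p = cfg.savgol_window, cfg.savgol_order
    if w % 2 != 1 or w <= p:
        raise ValidationError("savgol_window must be odd and > savgol_order")
    if isinstance(track, RigidPoseTrack):
        out = track.copy()
        for s, e in _runs(track.valid):
            if e - s < w:
                continue
            out.positions[s:e] = _savgol_span(track.positions[s:e], w, p)
            q = track.rotations[s:e].copy()
            for t in range(1, len(q)):  # hemisphere continuity before filtering
                if np.dot(q[t], q[t - 1]) < 0:
                    q[t] = -q[t]
            q = _savgol_span(q, w, p)
            q /= np.linalg.norm(q, axis=1, keepdims=True)
            out.rotations[s:e] = q
        return out
    if isinstance(track, HandJointTrack):
        out = track.copy()
        T = len(track)
        flat = track.joints.reshape(T, 2, 63)
        for h in range(2):
            for s, e in _runs(track.detected[:, h]):
                if e - s < w:
                    continue
                out.joints[s:e, h] = _savgol_span(flat[s:e, h], w, p).reshape(-1, 21, 3)
        return out
    raise TypeError(f"unsupported track type {type(track)!r}")


# ---------------------------------------------------------------- augmentation

FLIP_Y = np.diag([-1.0, 1.0, -1.0])  # Ry(180 deg)
FLIP_XZ = np.diag([1.0, -1.0, -1.0]) @ np.diag([-1.0, -1.0, 1.0])  # Rx(180)∘Rz(180)


def _apply_global_rotation(track: RigidPoseTrack, R: np.ndarray) -> None:
    track.positions[:] = track.positions @ R.T
    g = rotation_to_quat(Rotation.from_matrix(R))
    for t in range(len(track)):
        track.rotations[t] = quat_multiply(g, track.rotations[t])


def augment_tool_pose(track: RigidPoseTrack, cfg: Optional[PreprocessConfig] = None,
                      seed: int = 0) -> RigidPoseTrack:
    """Whole-video flip augmentations plus additive noise, deterministic in seed.

    With probability ``flip_probability`` each: a 180-degree rotation about y
    and a combined 180-degree rotation about x and z are applied rigidly to
    the whole video (positions rotated, rotations composed on the left).
    Gaussian noise of ``tool_noise_sigma`` is then added to every position
    coordinate, and rotations are perturbed about a random axis by an angle
    of the same magnitude in radians.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    rng = np.random.default_rng(seed)
    out = track.copy()
    if rng.random() < cfg.flip_probability:
        _apply_global_rotation(out, FLIP_Y)
    if rng.random() < cfg.flip_probability:
        _apply_global_rotation(out, FLIP_XZ)
    if cfg.tool_noise_sigma > 0:
        T = len(out)
        out.positions += rng.normal(0.0, cfg.tool_noise_sigma, size=(T, 3))
        axes = rng.normal(size=(T, 3))
        axes /= np.linalg.norm(axes, axis=1, keepdims=True)
        angles = rng.normal(0.0, cfg.tool_noise_sigma, size=T)
        dq = rotation_to_quat(Rotation.from_rotvec(axes * angles[:, None]))
        for t in range(T):
            out.rotations[t] = quat_multiply(dq[t], out.rotations[t])
        norms = np.linalg.norm(out.rotations, axis=1, keepdims=True)
        out.rotations /= norms
    return out


def augment_hand_pose(track: HandJointTrack, cfg: Optional[PreprocessConfig] = None,
                      seed: int = 0) -> HandJointTrack:
    """One random rotation about ``hand_rotation_axis`` applied to all joints
    of all frames (a rigid whole-video motion), deterministic in seed."""
    if cfg is None:
        cfg = PreprocessConfig()
    rng = np.random.default_rng(seed)
    angle = rng.uniform(0.0, 2.0 * np.pi)
    axis = np.asarray(cfg.hand_rotation_axis, dtype=np.float64)
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(axis * angle).as_matrix()
    out = track.copy()
    out.joints = out.joints @ R.T
    return out


# ---------------------------------------------------------------- features

def tracks_to_features(tools: Optional[Mapping[str, RigidPoseTrack]] = None,
                       hands: Optional[HandJointTrack] = None,
                       modality: str = "tools",
                       include_validity_flags: bool = True) -> FeatureSequence:
    """Flatten cleaned tracks into a per-frame feature matrix.

    ``tools``: per tool (sorted by id) 3 position + 4 quaternion + 1 validity
    flag; invalid frames are zero-filled with flag 0.  ``hands``: 126 joint
    coordinates + 2 per-hand validity flags.  D is a pure function of the
    modality and the tool count.  ``include_validity_flags=False`` drops the
    flag columns for a downstream model that should not see imputation state.
    """
    if modality == "tools":
        if not tools:
            raise ValidationError("modality 'tools' requires tool tracks")
        lengths = {len(tr) for tr in tools.values()}
        if len(lengths) != 1:
            raise ValidationError(f"tool tracks disagree on length: {sorted(lengths)}")
        cols = []
        for tool_id in sorted(tools):
            tr = tools[tool_id]
            valid = tr.valid.astype(np.float64)
            pos = np.where(tr.valid[:, None], tr.positions, 0.0)
            rot = np.where(tr.valid[:, None], tr.rotations, 0.0)
            parts = [pos, rot] + ([valid[:, None]] if include_validity_flags else [])
            cols.append(np.hstack(parts))
        return FeatureSequence(np.hstack(cols), "tools")
    if modality == "hands":
        if hands is None:
            raise ValidationError("modality 'hands' requires a hand track")
        T = len(hands)
        det = hands.detected
        joints = np.where(det[:, :, None, None], hands.joints, 0.0)
        parts = [joints.reshape(T, 126)]
        if include_validity_flags:
            parts.append(det.astype(np.float64))
        return FeatureSequence(np.hstack(parts), "hands")
    raise ValidationError(f"unsupported modality {modality!r} for pose features")


def preprocess_tool_track(track: RigidPoseTrack,
                          cfg: Optional[PreprocessConfig] = None,
                          symmetry: Optional[Sequence[np.ndarray]] = None,
                          ) -> RigidPoseTrack:
    """The full tool cleaning chain: disambiguate -> LOCF -> smooth."""
    if cfg is None:
        cfg = PreprocessConfig()
    track = disambiguate_tool_rotations(track, symmetry)
    track = impute_locf(track, cfg.max_gap_frames)
    return smooth_savitzky_golay(track, cfg)


def preprocess_hand_track(track: HandJointTrack,
                          cfg: Optional[PreprocessConfig] = None) -> HandJointTrack:
    """The full hand cleaning chain: interpolate gaps -> smooth."""
    if cfg is None:
        cfg = PreprocessConfig()
    track = interpolate_gaps_linear(track, cfg.max_gap_frames)
    return smooth_savitzky_golay(track, cfg)


__all__ = [
    "quat_to_rotation", "rotation_to_quat", "quat_multiply", "geodesic_angle",
    "IDENTITY_QUAT", "RY_180_QUAT", "DEFAULT_SYMMETRY", "FLIP_Y", "FLIP_XZ",
    "disambiguate_tool_rotations", "impute_locf", "interpolate_gaps_linear",
    "smooth_savitzky_golay", "augment_tool_pose", "augment_hand_pose",
    "tracks_to_features", "preprocess_tool_track", "preprocess_hand_track",
]
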