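"""Synthetic multi-surgeon suturing dataset generator.

Emulates the statistical structure of an open-surgery suturing dataset:
repeated gesture cycles (entering -> gripping -> passing, with occasional
'other' activity), per-class mean segment durations of 138/41/66/259 frames
at 30 FPS, two tracked tools (needle driver and tweezers) with symmetry
flips and detection dropout, two 21-joint hands, per-frame video embeddings,
and per-surgeon style offsets that make leave-one-user-out folds genuinely
harder than random splits.

Modality noises are drawn independently, so models trained on different
modalities make complementary errors — the regime in which logit-ensembling
pays off.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.spatial.transform import Rotation

from . import dataio
from .pose import RY_180_QUAT, quat_multiply, rotation_to_quat
from .types import (
    DEFAULT_FPS,
    DEFAULT_VOCABULARY,
    FeatureSequence,
    HandJointTrack,
    LabelSequence,
    RigidPoseTrack,
    ValidationError,
)

TOOL_IDS = ("needle_driver", "tweezers")


@dataclass
class SimulatorConfig:
    """Study conditions for the synthetic dataset.

    ``mean_durations`` holds the per-class mean segment lengths in frames
    (entering, gripping, passing, other); durations are negative-binomial
    with dispersion ``duration_dispersion`` (larger = closer to Poisson).
    ``p_other_per_cycle`` = 0.3 reproduces roughly 259 'other' segments per
    ~850 suturing cycles.  ``snr`` divides every modality's measurement
    noise, so one knob moves the whole dataset between clean and hard.
    """

    n_surgeons: int = 5
    videos_per_surgeon: int = 3
    cycles_per_video: int = 9
    mean_durations: tuple[float, float, float, float] = (138.0, 41.0, 66.0, 259.0)
    duration_dispersion: float = 10.0
    p_other_per_cycle: float = 0.3
    fps: float = DEFAULT_FPS
    tool_count: int = 2
    detection_dropout_rate: float = 0.05
    mean_gap_length: float = 4.0
    flip_rate: float = 0.02
    video_feature_dim: int = 64
    snr: float = 2.0
    noise_scale: float = 1.0
    surgeon_style_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_other_per_cycle", "detection_dropout_rate", "flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if any(m <= 0 for m in self.mean_durations):
            raise ValidationError("mean durations must be positive")
        if self.n_surgeons < 3:
            raise ValidationError("need >= 3 surgeons for LOUO folds")
        if self.tool_count != len(TOOL_IDS):
            raise ValidationError(f"tool_count must be {len(TOOL_IDS)}")
        if self.snr <= 0:
            raise ValidationError("snr must be positive")


ENTERING, GRIPPING, PASSING, OTHER = 0, 1, 2, 3


# ---------------------------------------------------------------- labels

def _nb_duration(mean: float, dispersion: float, rng: np.random.Generator) -> int:
    """Negative-binomial segment duration with the configured mean, >= 1 frame."""
    p = dispersion / (dispersion + mean)
    return max(1, int(rng.negative_binomial(dispersion, p)))


def simulate_label_sequence(cfg: SimulatorConfig, rng: np.random.Generator,
                            n_cycles: Optional[int] = None) -> LabelSequence:
    """Cycles of entering -> gripping -> passing with occasional 'other'.

    After each suturing cycle an 'other' segment is inserted with
    probability ``p_other_per_cycle``.
    """
    if n_cycles is None:
        n_cycles = cfg.cycles_per_video
    if n_cycles < 1:
        raise ValidationError("need at least one cycle")
    parts = []
    for _ in range(n_cycles):
        for cls in (ENTERING, GRIPPING, PASSING):
            parts.append(np.full(_nb_duration(cfg.mean_durations[cls],
                                              cfg.duration_dispersion, rng),
                                 cls, dtype=np.int64))
        if rng.random() < cfg.p_other_per_cycle:
            parts.append(np.full(_nb_duration(cfg.mean_durations[OTHER],
                                              cfg.duration_dispersion, rng),
                                 OTHER, dtype=np.int64))
    return LabelSequence(np.concatenate(parts), DEFAULT_VOCABULARY, cfg.fps)


# ---------------------------------------------------------------- styles

@dataclass
class SurgeonStyle:
    """Additive per-surgeon offsets in trajectory and feature space."""

    tool_offsets: dict
    hand_offset: np.ndarray
    feature_offset: np.ndarray


def draw_surgeon_style(cfg: SimulatorConfig, rng: np.random.Generator) -> SurgeonStyle:
    s = cfg.surgeon_style_sigma
    return SurgeonStyle(
        tool_offsets={tid: rng.normal(0.0, s, size=3) for tid in TOOL_IDS},
        hand_offset=rng.normal(0.0, s, size=3),
        feature_offset=_unit(rng.normal(size=cfg.video_feature_dim)) * s * 2.0,
    )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------- tools

# Per-tool, per-class trajectory templates: base position, motion amplitude,
# and target rotation vector (radians).  Values are in arbitrary track units
# with class separation of order 1.
_TOOL_BASE = {
    "needle_driver": np.array([
        [0.0, 0.0, 0.0],   # entering
        [1.2, 0.3, 0.2],   # gripping
        [0.4, 1.0, 0.6],   # passing
        [2.0, 1.5, 1.5],   # other
    ]),
    "tweezers": np.array([
        [1.0, 0.2, 0.8],
        [0.1, 1.1, 0.3],
        [1.4, 1.2, 0.1],
        [2.2, 0.4, 1.8],
    ]),
}
_TOOL_AMP = {
    "needle_driver": np.array([[0.5, 0.2, 0.3], [0.2, 0.4, 0.1],
                               [0.4, 0.3, 0.5], [0.3, 0.3, 0.3]]),
    "tweezers": np.array([[0.3, 0.4, 0.2], [0.4, 0.2, 0.4],
                          [0.2, 0.5, 0.3], [0.3, 0.3, 0.3]]),
}
_TOOL_ROTVEC = {
    "needle_driver": np.array([[0.0, 0.0, 0.0], [0.9, 0.2, 0.0],
                               [0.3, 0.9, 0.5], [1.2, 1.0, 1.0]]),
    "tweezers": np.array([[0.5, 0.0, 0.4], [0.0, 0.8, 0.2],
                          [0.9, 0.4, 0.0], [1.0, 1.4, 0.6]]),
}
ROT_SMOOTH_WINDOW = 15  # frames; bounds frame-to-frame template rotation steps
NOISE_SMOOTH_WINDOW = 9  # estimator errors persist across neighbouring frames


def _correlated_noise(rng: np.random.Generator, shape: tuple, sigma: float
                      ) -> np.ndarray:
    """Temporally correlated Gaussian noise with per-frame std ``sigma``.

    White noise box-filtered along the first (time) axis and rescaled, so a
    temporal model cannot trivially average it away — mimicking the slowly
    drifting errors of upstream pose estimators.
    """
    w = NOISE_SMOOTH_WINDOW
    noise = uniform_filter1d(rng.normal(size=shape), w, axis=0, mode="nearest")
    return noise * (sigma * np.sqrt(w))


def _segment_phase(labels: np.ndarray) -> np.ndarray:
    """Phase u in [0, 1] of each frame within its segment."""
    u = np.zeros(len(labels))
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[t - 1]:
            length = t - start
            u[start:t] = (np.arange(length) + 0.5) / length
            start = t
    return u


def _dropout_mask(T: int, cfg: SimulatorConfig, rng: np.random.Generator
                  ) -> np.ndarray:
    """Detection mask with geometric-length gaps at the configured rate."""
    detected = np.ones(T, dtype=bool)
    if cfg.detection_dropout_rate <= 0:
        return detected
    p_start = cfg.detection_dropout_rate / (
        (1.0 - cfg.detection_dropout_rate) * cfg.mean_gap_length)
    t = 0
    while t < T:
        if rng.random() < p_start:
            gap = int(rng.geometric(1.0 / cfg.mean_gap_length))
            detected[t:t + gap] = False
            t += gap
        else:
            t += 1
    return detected


def simulate_tool_tracks(labels: LabelSequence, cfg: SimulatorConfig,
                         style: SurgeonStyle, rng: np.random.Generator
                         ) -> dict[str, RigidPoseTrack]:
    """Class-templated smooth tool motion with flips, noise and dropout.

    The underlying template rotation path is a temporally smoothed
    class-target rotation-vector track, so consecutive template rotations
    differ by a small bounded geodesic step; symmetry flips and measurement
    noise are layered on top.
    """
    y = labels.labels
    T = len(y)
    u = _segment_phase(y)
    sigma = cfg.noise_scale / cfg.snr
    tracks = {}
    for tid in TOOL_IDS:
        base = _TOOL_BASE[tid][y]
        amp = _TOOL_AMP[tid][y]
        pos = base + amp * np.sin(np.pi * u)[:, None] + style.tool_offsets[tid]
        pos = pos + _correlated_noise(rng, (T, 3), sigma)
        rotvec = uniform_filter1d(_TOOL_ROTVEC[tid][y], ROT_SMOOTH_WINDOW,
                                  axis=0, mode="nearest")
        rot = Rotation.from_rotvec(rotvec)
        noise_vec = _correlated_noise(rng, (T, 3), sigma)
        quat = rotation_to_quat(Rotation.from_rotvec(noise_vec) * rot)
        flips = rng.random(T) < cfg.flip_rate
        for t in np.flatnonzero(flips):
            quat[t] = quat_multiply(quat[t], RY_180_QUAT)
        quat /= np.linalg.norm(quat, axis=1, keepdims=True)
        detected = _dropout_mask(T, cfg, rng)
        tracks[tid] = RigidPoseTrack(pos, quat, detected, tid)
    return tracks


def tool_template_track(labels: LabelSequence, tool_id: str,
                        style: Optional[SurgeonStyle] = None) -> RigidPoseTrack:
    """Noise-free, flip-free, fully detected template track (ground truth)."""
    y = labels.labels
    u = _segment_phase(y)
    offset = style.tool_offsets[tool_id] if style is not None else 0.0
    pos = _TOOL_BASE[tool_id][y] + _TOOL_AMP[tool_id][y] * np.sin(np.pi * u)[:, None] \
        + offset
    rotvec = uniform_filter1d(_TOOL_ROTVEC[tool_id][y], ROT_SMOOTH_WINDOW,
                              axis=0, mode="nearest")
    quat = rotation_to_quat(Rotation.from_rotvec(rotvec))
    return RigidPoseTrack(pos, quat, np.ones(len(y), dtype=bool), tool_id)


# ---------------------------------------------------------------- hands

def _hand_template() -> np.ndarray:
    """Canonical 21-joint hand: wrist + 5 fingers x 4 joints, palm in x-y."""
    joints = [np.zeros(3)]
    angles = np.linspace(-0.6, 0.6, 5)
    for f, ang in enumerate(angles):
        direction = np.array([np.sin(ang), np.cos(ang), 0.0])
        length = 0.9 if f else 0.7  # thumb shorter
        for k in range(1, 5):
            joints.append(direction * length * k / 4.0)
    return np.stack(joints)  # (21, 3)


HAND_TEMPLATE = _hand_template()
# Class-dependent articulation: finger curl factor plus out-of-plane pitch.
_HAND_CURL = np.array([1.0, 0.55, 0.8, 1.25])
_HAND_PITCH = np.array([0.0, 0.5, -0.4, 0.9])
_HAND_TOOL = {0: "needle_driver", 1: "tweezers"}  # L follows driver, R tweezers
_HAND_WRIST_OFFSET = np.array([[0.0, -0.5, 0.3], [0.0, -0.5, -0.3]])


def hand_shape(cls: int) -> np.ndarray:
    """Rigid 21-joint shape for one articulation state (gesture class)."""
    shaped = HAND_TEMPLATE * _HAND_CURL[cls]
    R = Rotation.from_rotvec([_HAND_PITCH[cls], 0.0, 0.0]).as_matrix()
    return shaped @ R.T


_HAND_SHAPES = np.stack([hand_shape(c) for c in range(4)])  # (4, 21, 3)


def simulate_hand_tracks(labels: LabelSequence, cfg: SimulatorConfig,
                         style: SurgeonStyle, rng: np.random.Generator
                         ) -> HandJointTrack:
    """Two hands whose wrists follow their tools with class-dependent shape."""
    y = labels.labels
    T = len(y)
    sigma = cfg.noise_scale / cfg.snr
    joints = np.zeros((T, 2, 21, 3))
    detected = np.zeros((T, 2), dtype=bool)
    for h in range(2):
        tool = tool_template_track(labels, _HAND_TOOL[h], style)
        wrist = tool.positions + _HAND_WRIST_OFFSET[h] + style.hand_offset
        joints[:, h] = wrist[:, None, :] + _HAND_SHAPES[y]
        # wrist-level drift shared by all joints (depth ambiguity) plus
        # smaller per-joint jitter; both temporally correlated
        joints[:, h] += _correlated_noise(rng, (T, 3), sigma)[:, None, :]
        joints[:, h] += _correlated_noise(rng, (T, 21, 3), sigma / 3.0)
        detected[:, h] = _dropout_mask(T, cfg, rng)
    return HandJointTrack(joints, detected)


# ---------------------------------------------------------------- video

PROTOTYPE_NORM = 2.0  # embedding prototype norm; sets video-class margin vs noise


def class_prototypes(cfg: SimulatorConfig) -> np.ndarray:
    """Fixed per-class embedding prototypes, deterministic in cfg.seed."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0xF00D]))
    protos = rng.normal(size=(4, cfg.video_feature_dim))
    protos /= np.linalg.norm(protos, axis=1, keepdims=True)
    return protos * PROTOTYPE_NORM


def simulate_video_features(labels: LabelSequence, cfg: SimulatorConfig,
                            style: SurgeonStyle, rng: np.random.Generator,
                            prototypes: Optional[np.ndarray] = None
                            ) -> FeatureSequence:
    """Per-frame embedding = class prototype + surgeon style + smoothed noise."""
    if prototypes is None:
        prototypes = class_prototypes(cfg)
    T = len(labels)
    noise = _correlated_noise(rng, (T, cfg.video_feature_dim),
                              cfg.noise_scale / cfg.snr)
    values = prototypes[labels.labels] + style.feature_offset + noise
    return FeatureSequence(values, "video")


# ---------------------------------------------------------------- dataset

@dataclass
class VideoRecord:
    """One simulated video: raw labels, tracks and embeddings."""

    video_id: str
    surgeon: str
    labels: LabelSequence
    tools: dict
    hands: HandJointTrack
    video_features: FeatureSequence


def generate_dataset(cfg: SimulatorConfig) -> list[VideoRecord]:
    """Simulate the full multi-surgeon dataset in memory, fully seeded."""
    root = np.random.SeedSequence(cfg.seed)
    style_rng = np.random.default_rng(root.spawn(1)[0])
    protos = class_prototypes(cfg)
    records = []
    for s in range(cfg.n_surgeons):
        surgeon = f"surgeon_{s:02d}"
        style = draw_surgeon_style(cfg, style_rng)
        for v in range(cfg.videos_per_surgeon):
            rng = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 1 + s, v]))
            labels = simulate_label_sequence(cfg, rng)
            records.append(VideoRecord(
                video_id=f"{surgeon}_video_{v:02d}",
                surgeon=surgeon,
                labels=labels,
                tools=simulate_tool_tracks(labels, cfg, style, rng),
                hands=simulate_hand_tracks(labels, cfg, style, rng),
                video_features=simulate_video_features(labels, cfg, style, rng,
                                                       protos),
            ))
    return records


def make_dataset(cfg: SimulatorConfig, out_dir: str) -> dict:
    """Write the simulated dataset to disk and return the manifest.

    Per video: label CSV, tool-pose CSV, hand-pose CSV and a video-feature
    matrix with JSON sidecar; plus ``manifest.json`` listing surgeon ids and
    file paths.  Byte-identical across runs with the same config.
    """
    os.makedirs(out_dir, exist_ok=True)
    records = generate_dataset(cfg)
    manifest = {"seed": cfg.seed, "fps": cfg.fps,
                "vocabulary": list(DEFAULT_VOCABULARY), "videos": []}
    for rec in records:
        base = os.path.join(out_dir, rec.video_id)
        paths = {
            "labels": base + "_labels.csv",
            "tools": base + "_tools.csv",
            "hands": base + "_hands.csv",
            "video_features": base + "_video.csv",
        }
        dataio.write_frame_labels(rec.labels, paths["labels"])
        dataio.write_tool_pose_table(rec.tools, paths["tools"])
        dataio.write_hand_pose_table(rec.hands, paths["hands"])
        dataio.write_feature_matrix(rec.video_features, paths["video_features"])
        manifest["videos"].append({
            "video_id": rec.video_id, "surgeon": rec.surgeon,
            **{k: os.path.basename(p) for k, p in paths.items()},
        })
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_dataset(out_dir: str) -> list[VideoRecord]:
    """Read a dataset previously written by :func:`make_dataset`."""
    with open(os.path.join(out_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    records = []
    for entry in manifest["videos"]:
        records.append(VideoRecord(
            video_id=entry["video_id"],
            surgeon=entry["surgeon"],
            labels=dataio.read_frame_labels(
                os.path.join(out_dir, entry["labels"]),
                manifest["vocabulary"], manifest["fps"]),
            tools=dataio.read_tool_pose_table(os.path.join(out_dir, entry["tools"])),
            hands=dataio.read_hand_pose_table(os.path.join(out_dir, entry["hands"])),
            video_features=dataio.read_feature_matrix(
                os.path.join(out_dir, entry["video_features"])),
        ))
    return records


__all__ = [
    "SimulatorConfig", "SurgeonStyle", "VideoRecord", "TOOL_IDS",
    "simulate_label_sequence", "draw_surgeon_style", "simulate_tool_tracks",
    "tool_template_track", "simulate_hand_tracks", "simulate_video_features",
    "class_prototypes", "hand_shape", "generate_dataset", "make_dataset",
    "load_dataset", "HAND_TEMPLATE", "ROT_SMOOTH_WINDOW",
]
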