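"""Core data containers for the gesture-recognition pipeline.

The pipeline's currency is a handful of small validated containers:
frame-wise labels and their run-length segment form, per-frame feature
matrices, rigid 6-DoF tool tracks, two-hand 21-joint tracks, and
unnormalized per-frame class scores (logits).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

DEFAULT_VOCABULARY: tuple[str, ...] = ("entering", "gripping", "passing", "other")
DEFAULT_FPS: float = 30.0

MODALITIES = ("video", "tools", "hands", "concat")


class ValidationError(ValueError):
    """An input violates a container invariant or a file-format contract."""


@dataclass
class LabelSequence:
    """Frame-wise class labels for one video.

    ``labels[f]`` is the integer class id of frame ``f``; ids index into
    ``vocabulary``.
    """

    labels: np.ndarray
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY
    fps: float = DEFAULT_FPS

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.vocabulary = tuple(self.vocabulary)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValidationError("labels must be a non-empty 1-D array")
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        if len(self.vocabulary) < 1:
            raise ValidationError("vocabulary must be non-empty")
        if self.labels.min() < 0 or self.labels.max() >= len(self.vocabulary):
            raise ValidationError(
                "label ids must lie in [0, %d)" % len(self.vocabulary)
            )

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def n_classes(self) -> int:
        return len(self.vocabulary)

    def class_names(self) -> list[str]:
        return [self.vocabulary[i] for i in self.labels]


@dataclass
class Segmentation:
    """Run-length form of a label sequence: ordered (class id, start, end).

    Intervals are half-open ``[start, end)``, contiguous from frame 0, and
    adjacent segments carry different class ids.
    """

    segments: list[tuple[int, int, int]]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValidationError("segmentation must contain at least one segment")
        prev_end = 0
        prev_cls: Optional[int] = None
        for cls, start, end in self.segments:
            if start != prev_end:
                raise ValidationError(
                    f"segments must be contiguous: expected start {prev_end}, got {start}"
                )
            if end <= start:
                raise ValidationError(f"empty segment ({cls},{start},{end})")
            if prev_cls is not None and cls == prev_cls:
                raise ValidationError("adjacent segments must differ in class")
            prev_end, prev_cls = end, cls

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def n_frames(self) -> int:
        return self.segments[-1][2]

    def class_sequence(self) -> list[int]:
        return [cls for cls, _, _ in self.segments]


@dataclass
class EventRecord:
    """A BORIS-style behavioural event: behaviour name plus start/stop seconds."""

    behavior: str
    start_s: float
    stop_s: float

    def __post_init__(self) -> None:
        if not (self.stop_s > self.start_s >= 0.0):
            raise ValidationError(
                f"event requires stop_s > start_s >= 0, got ({self.start_s}, {self.stop_s})"
            )


@dataclass
class FeatureSequence:
    """A T x D per-frame feature matrix with a modality tag and frame stride."""

    values: np.ndarray
    modality: str = "video"
    stride: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValidationError("values must be a T x D matrix with T, D >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature values must be finite")
        if self.modality not in MODALITIES:
            raise ValidationError(f"unknown modality {self.modality!r}")
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class LogitSequence:
    """T x C unnormalized class scores; the object the ensemble averages."""

    values: np.ndarray
    stride: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("logits must be a T x C matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("logits must be finite")
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]

    def argmax_labels(self, vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY,
                      fps: float = DEFAULT_FPS) -> LabelSequence:
        # np.argmax breaks ties toward the lowest class index by construction
        return LabelSequence(np.argmax(self.values, axis=1), vocabulary, fps)


@dataclass
class RigidPoseTrack:
    """Per-tool time series of 3-D position + unit-quaternion rotation.

    Quaternions are scalar-first ``(qw, qx, qy, qz)``, right-handed.
    ``detected`` marks frames where the upstream estimator produced a pose;
    ``imputed`` marks frames later filled by gap imputation.  A frame is
    *valid* if detected or imputed.
    """

    positions: np.ndarray
    rotations: np.ndarray
    detected: np.ndarray
    tool_id: str = "tool"
    imputed: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.rotations = np.asarray(self.rotations, dtype=np.float64)
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.imputed is None:
            self.imputed = np.zeros(self.detected.shape, dtype=bool)
        else:
            self.imputed = np.asarray(self.imputed, dtype=bool)
        T = self.detected.size
        if self.positions.shape != (T, 3):
            raise ValidationError("positions must be T x 3")
        if self.rotations.shape != (T, 4):
            raise ValidationError("rotations must be T x 4 quaternions")
        if self.imputed.shape != (T,):
            raise ValidationError("imputed mask length mismatch")
        valid = self.valid
        if valid.any():
            norms = np.linalg.norm(self.rotations[valid], axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise ValidationError("quaternions at valid frames must be unit norm")

    def __len__(self) -> int:
        return int(self.detected.size)

    @property
    def valid(self) -> np.ndarray:
        return self.detected | self.imputed

    def copy(self) -> "RigidPoseTrack":
        return RigidPoseTrack(
            self.positions.copy(), self.rotations.copy(), self.detected.copy(),
            self.tool_id, self.imputed.copy(),
        )


@dataclass
class HandJointTrack:
    """Per-frame 2 x 21 x 3 hand-joint coordinates with per-hand detection mask.

    Hand order is (left, right); the joint order follows the upstream
    21-keypoint hand skeleton.
    """

    joints: np.ndarray
    detected: np.ndarray

    HANDS: tuple[str, str] = ("L", "R")
    N_JOINTS: int = 21

    def __post_init__(self) -> None:
        self.joints = np.asarray(self.joints, dtype=np.float64)
        self.detected = np.asarray(self.detected, dtype=bool)
        if self.joints.ndim != 4 or self.joints.shape[1:] != (2, 21, 3):
            raise ValidationError("joints must be T x 2 x 21 x 3")
        if self.detected.shape != (self.joints.shape[0], 2):
            raise ValidationError("detected mask must be T x 2")

    def __len__(self) -> int:
        return int(self.joints.shape[0])

    def copy(self) -> "HandJointTrack":
        return HandJointTrack(self.joints.copy(), self.detected.copy())


@dataclass
class PreprocessConfig:
    """Knobs for pose cleaning, smoothing and augmentation.

    ``max_gap_frames`` bounds both LOCF imputation (tools) and linear
    interpolation (hands) at 10 frames (1/3 s at 30 FPS).  The Savitzky-Golay
    window/order default to a mild 9-frame quadratic fit that preserves
    gesture-scale dynamics at 30 FPS.
    """

    max_gap_frames: int = 10
    savgol_window: int = 9
    savgol_order: int = 2
    tool_noise_sigma: float = 0.01
    hand_rotation_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    flip_probability: float = 0.5

    def __post_init__(self) -> None:
        if self.savgol_window % 2 != 1 or self.savgol_window <= self.savgol_order:
            raise ValidationError("savgol_window must be odd and > savgol_order")
        if self.max_gap_frames < 0:
            raise ValidationError("max_gap_frames must be >= 0")
        if not 0.0 <= self.flip_probability <= 1.0:
            raise ValidationError("flip_probability must lie in [0, 1]")


@dataclass
class ModelConfig:
    """MS-TCN++ hyper-parameters.

    ``L`` is the layer count shared by the prediction-generation and
    refinement stages; ``S`` the total stage count (one prediction stage plus
    S-1 refinements).  ``lambda_smooth`` and ``tau`` parameterize the
    truncated-MSE smoothing term added to the frame cross-entropy.
    """

    L: int = 5
    S: int = 2
    lr: float = 1e-3
    hidden_width: int = 128
    lambda_smooth: float = 0.15
    tau: float = 4.0
    dropout: float = 0.5
    input_batchnorm: bool = False
    stride: int = 1
    epochs: int = 30
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValidationError("L must be >= 1")
        if self.S < 2:
            raise ValidationError("S must be >= 2 (prediction + >=1 refinement)")
        if self.hidden_width < 1:
            raise ValidationError("hidden_width must be >= 1")
        if self.tau <= 0:
            raise ValidationError("tau must be positive")
        if self.lambda_smooth < 0:
            raise ValidationError("lambda_smooth must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValidationError("dropout must lie in [0, 1)")
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")


@dataclass
class MetricsReport:
    """One evaluation row: frame accuracy, segmental edit score, frame-wise
    macro F1 and overlap F1 at IoU 0.10/0.25/0.50, all as percents."""

    accuracy: float
    edit: float
    f1_macro: float
    f1_at_10: float
    f1_at_25: float
    f1_at_50: float
    per_video: Optional[dict] = None

    METRIC_FIELDS = ("accuracy", "edit", "f1_macro", "f1_at_10", "f1_at_25", "f1_at_50")

    def __post_init__(self) -> None:
        for name in self.METRIC_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name}={v} outside [0, 100]")

    def as_dict(self) -> dict:
        d = {name: float(getattr(self, name)) for name in self.METRIC_FIELDS}
        if self.per_video is not None:
            d["per_video"] = {k: dict(v) for k, v in self.per_video.items()}
        return d


__all__ = [
    "DEFAULT_VOCABULARY", "DEFAULT_FPS", "MODALITIES", "ValidationError",
    "LabelSequence", "Segmentation", "EventRecord", "FeatureSequence",
    "LogitSequence", "RigidPoseTrack", "HandJointTrack",
    "PreprocessConfig", "ModelConfig", "MetricsReport",
]
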