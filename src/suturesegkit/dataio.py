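"""Readers and writers for on-disk artifacts.

All tabular formats are plain CSV; feature matrices are headerless delimited
text with a JSON sidecar (``<path>.json``) carrying modality and stride.
Readers validate strictly and raise :class:`ValidationError`; the only
silent coercion is renormalization of quaternions within 1e-3 of unit norm.
"""
from __future__ import annotations

import json
import os
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_FPS,
    DEFAULT_VOCABULARY,
    EventRecord,
    FeatureSequence,
    HandJointTrack,
    LabelSequence,
    LogitSequence,
    RigidPoseTrack,
    Segmentation,
    ValidationError,
)

QUAT_NORM_TOL = 1e-3


# ---------------------------------------------------------------- labels

def read_frame_labels(path, vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
                      fps: float = DEFAULT_FPS) -> LabelSequence:
    """Read a ``frame,label`` CSV into a :class:`LabelSequence`.

    Frames must be 0-based and consecutive; label strings must belong to
    ``vocabulary``.
    """
    df = pd.read_csv(path)
    if list(df.columns) != ["frame", "label"]:
        raise ValidationError(f"{path}: expected header 'frame,label', got {list(df.columns)}")
    if len(df) == 0:
        raise ValidationError(f"{path}: empty label file")
    frames = df["frame"].to_numpy()
    if frames.dtype.kind not in "iu":
        raise ValidationError(f"{path}: non-integer frame indices")
    if len(np.unique(frames)) != len(frames):
        raise ValidationError(f"{path}: duplicate frame index")
    if not np.array_equal(frames, np.arange(len(frames))):
        raise ValidationError(f"{path}: non-consecutive frames (must run 0..T-1)")
    index = {name: i for i, name in enumerate(vocabulary)}
    ids = np.empty(len(df), dtype=np.int64)
    for i, name in enumerate(df["label"]):
        if name not in index:
            raise ValidationError(f"{path}: unknown class {name!r}")
        ids[i] = index[name]
    return LabelSequence(ids, tuple(vocabulary), fps)


def write_frame_labels(seq: LabelSequence, path) -> None:
    df = pd.DataFrame({"frame": np.arange(len(seq)), "label": seq.class_names()})
    df.to_csv(path, index=False)


# ---------------------------------------------------------------- BORIS events

def read_events(path) -> list[EventRecord]:
    """Read a ``behavior,start_s,stop_s`` CSV of behavioural events."""
    df = pd.read_csv(path)
    if list(df.columns) != ["behavior", "start_s", "stop_s"]:
        raise ValidationError(
            f"{path}: expected header 'behavior,start_s,stop_s', got {list(df.columns)}")
    return [EventRecord(str(r.behavior), float(r.start_s), float(r.stop_s))
            for r in df.itertuples()]


def write_events(events: Iterable[EventRecord], path) -> None:
    df = pd.DataFrame([(e.behavior, e.start_s, e.stop_s) for e in events],
                      columns=["behavior", "start_s", "stop_s"])
    df.to_csv(path, index=False)


def events_to_frame_labels(events: Sequence[EventRecord], fps: float = DEFAULT_FPS,
                           n_frames: int = 1,
                           fill_class: str = "other",
                           vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
                           on_overrun: str = "error") -> LabelSequence:
    """Rasterize timed events onto a frame grid.

    Frame ``f`` (time ``f/fps``) takes the class of the event covering it,
    i.e. with ``start_s <= f/fps < stop_s``; uncovered frames take
    ``fill_class``.  Events must be non-overlapping.  An event extending past
    ``n_frames/fps`` raises unless ``on_overrun='clip'``.
    """
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    if on_overrun not in ("error", "clip"):
        raise ValidationError("on_overrun must be 'error' or 'clip'")
    vocabulary = tuple(vocabulary)
    index = {name: i for i, name in enumerate(vocabulary)}
    if fill_class not in index:
        raise ValidationError(f"fill class {fill_class!r} not in vocabulary")
    ordered = sorted(events, key=lambda e: e.start_s)
    for a, b in zip(ordered, ordered[1:]):
        if b.start_s < a.stop_s:
            raise ValidationError(
                f"overlapping events: ({a.behavior},{a.start_s},{a.stop_s}) and "
                f"({b.behavior},{b.start_s},{b.stop_s})")
    duration = n_frames / fps
    labels = np.full(n_frames, index[fill_class], dtype=np.int64)
    for ev in ordered:
        if ev.behavior not in index:
            raise ValidationError(f"unknown class {ev.behavior!r}")
        if ev.stop_s > duration and on_overrun == "error":
            raise ValidationError(
                f"event ({ev.behavior},{ev.start_s},{ev.stop_s}) extends beyond "
                f"{duration:.6g} s ({n_frames} frames at {fps} FPS)")
        # frame f covered iff start_s <= f/fps < stop_s
        first = int(np.ceil(ev.start_s * fps - 1e-9))
        last = int(np.ceil(ev.stop_s * fps - 1e-9))  # exclusive
        first, last = max(first, 0), min(last, n_frames)
        if first < last:
            labels[first:last] = index[ev.behavior]
    return LabelSequence(labels, vocabulary, fps)


def segments_to_events(seg: Segmentation, fps: float,
                       vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
                       skip_class: Optional[str] = "other") -> list[EventRecord]:
    """Inverse of :func:`events_to_frame_labels` up to 1/fps quantization.

    Segments of ``skip_class`` (the uncovered-frame filler) are omitted.
    """
    vocabulary = tuple(vocabulary)
    out = []
    for cls, start, end in seg.segments:
        name = vocabulary[cls]
        if skip_class is not None and name == skip_class:
            continue
        out.append(EventRecord(name, start / fps, end / fps))
    return out


# ---------------------------------------------------------------- tool poses

TOOL_COLUMNS = ["frame", "tool_id", "x", "y", "z", "qw", "qx", "qy", "qz", "detected"]


def read_tool_pose_table(path) -> dict[str, RigidPoseTrack]:
    """Read a long-format tool-pose CSV into one track per tool id.

    Quaternions at detected frames are renormalized if within 1e-3 of unit
    norm, rejected otherwise.  Undetected frames carry a missing marker
    regardless of their stored coordinates.
    """
    df = pd.read_csv(path)
    if list(df.columns) != TOOL_COLUMNS:
        raise ValidationError(f"{path}: expected header {','.join(TOOL_COLUMNS)}")
    if df.duplicated(["frame", "tool_id"]).any():
        dup = df[df.duplicated(["frame", "tool_id"])].iloc[0]
        raise ValidationError(f"{path}: duplicate (frame={dup.frame}, tool_id={dup.tool_id})")
    if not df["detected"].isin((0, 1)).all():
        raise ValidationError(f"{path}: detected column must be 0/1")
    tracks: dict[str, RigidPoseTrack] = {}
    for tool_id, sub in df.groupby("tool_id", sort=True):
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(len(frames))):
            raise ValidationError(f"{path}: tool {tool_id!r} frames must run 0..T-1")
        pos = sub[["x", "y", "z"]].to_numpy(dtype=np.float64)
        quat = sub[["qw", "qx", "qy", "qz"]].to_numpy(dtype=np.float64)
        detected = sub["detected"].to_numpy(dtype=bool)
        norms = np.linalg.norm(quat[detected], axis=1)
        if np.any(np.abs(norms - 1.0) > QUAT_NORM_TOL):
            bad = frames[detected][np.abs(norms - 1.0) > QUAT_NORM_TOL][0]
            raise ValidationError(
                f"{path}: non-unit quaternion (tool {tool_id!r}, frame {bad})")
        quat[detected] /= norms[:, None]
        quat[~detected] = (1.0, 0.0, 0.0, 0.0)  # placeholder, masked
        tracks[str(tool_id)] = RigidPoseTrack(pos, quat, detected, str(tool_id))
    return tracks


def write_tool_pose_table(tracks: Mapping[str, RigidPoseTrack], path) -> None:
    rows = []
    for tool_id in sorted(tracks):
        tr = tracks[tool_id]
        for f in range(len(tr)):
            rows.append((f, tool_id, *tr.positions[f], *tr.rotations[f],
                         int(tr.detected[f])))
    pd.DataFrame(rows, columns=TOOL_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------- hand poses

def _hand_columns() -> list[str]:
    cols = ["frame", "hand", "detected"]
    for j in range(21):
        cols += [f"x{j:02d}", f"y{j:02d}", f"z{j:02d}"]
    return cols


HAND_COLUMNS = _hand_columns()


def read_hand_pose_table(path) -> HandJointTrack:
    """Read a per-frame, per-hand 21-joint CSV (63 coordinate columns)."""
    df = pd.read_csv(path)
    n_coord = len(df.columns) - 3
    if list(df.columns[:3]) != ["frame", "hand", "detected"] or n_coord != 63:
        if n_coord != 63:
            raise ValidationError(f"{path}: expected 63 coordinates, got {n_coord}")
        raise ValidationError(f"{path}: expected header {','.join(HAND_COLUMNS[:4])},...")
    if not df["hand"].isin(("L", "R")).all():
        bad = df.loc[~df["hand"].isin(("L", "R")), "hand"].iloc[0]
        raise ValidationError(f"{path}: hand must be 'L' or 'R', got {bad!r}")
    T = int(df["frame"].max()) + 1
    joints = np.zeros((T, 2, 21, 3))
    detected = np.zeros((T, 2), dtype=bool)
    seen = np.zeros((T, 2), dtype=bool)
    coords = df[df.columns[3:]].to_numpy(dtype=np.float64)
    for i, row in enumerate(df.itertuples()):
        h = 0 if row.hand == "L" else 1
        f = int(row.frame)
        if seen[f, h]:
            raise ValidationError(f"{path}: duplicate (frame={f}, hand={row.hand})")
        seen[f, h] = True
        joints[f, h] = coords[i].reshape(21, 3)
        detected[f, h] = bool(row.detected)
    return HandJointTrack(joints, detected)


def write_hand_pose_table(track: HandJointTrack, path) -> None:
    rows = []
    for f in range(len(track)):
        for h, hand in enumerate(HandJointTrack.HANDS):
            rows.append((f, hand, int(track.detected[f, h]),
                         *track.joints[f, h].ravel()))
    pd.DataFrame(rows, columns=HAND_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------- matrices

def _sidecar(path) -> str:
    return str(path) + ".json"


def write_feature_matrix(seq: FeatureSequence, path) -> None:
    """Write a feature matrix as headerless CSV plus a JSON metadata sidecar."""
    np.savetxt(path, seq.values, delimiter=",", fmt="%.17g")
    with open(_sidecar(path), "w") as fh:
        json.dump({"modality": seq.modality, "stride": seq.stride}, fh)


def read_feature_matrix(path) -> FeatureSequence:
    try:
        values = np.loadtxt(path, delimiter=",", ndmin=2)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{path}: non-finite entries")
    meta = {"modality": "video", "stride": 1}
    if os.path.exists(_sidecar(path)):
        with open(_sidecar(path)) as fh:
            meta.update(json.load(fh))
    return FeatureSequence(values, meta["modality"], int(meta["stride"]))


def write_logits(seq: LogitSequence, path) -> None:
    np.savetxt(path, seq.values, delimiter=",", fmt="%.17g")
    with open(_sidecar(path), "w") as fh:
        json.dump({"stride": seq.stride}, fh)


def read_logits(path) -> LogitSequence:
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    stride = 1
    if os.path.exists(_sidecar(path)):
        with open(_sidecar(path)) as fh:
            stride = int(json.load(fh).get("stride", 1))
    return LogitSequence(values, stride)


# ---------------------------------------------------------------- reports

def write_metrics_report(report: dict, path) -> None:
    """Write a metric report (per-fold values + mean/std per metric) as JSON."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)


def read_metrics_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


__all__ = [
    "read_frame_labels", "write_frame_labels", "read_events", "write_events",
    "events_to_frame_labels", "segments_to_events",
    "read_tool_pose_table", "write_tool_pose_table",
    "read_hand_pose_table", "write_hand_pose_table",
    "read_feature_matrix", "write_feature_matrix",
    "read_logits", "write_logits",
    "write_metrics_report", "read_metrics_report",
    "TOOL_COLUMNS", "HAND_COLUMNS",
]
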