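"""Leave-one-user-out cross-validation and the modality experiment matrix.

Each fold holds one surgeon's videos out for validation and another's for
testing, with the rest training — all ordered (validation, test) pairs, so
n surgeons give n*(n-1) folds.  Per fold and modality combination the
harness trains one model per single modality plus one on the concatenated
features, then evaluates the straightforward (concatenated) predictions and
the smoothed logit-ensemble predictions.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .fusion import average_logits, concat_modalities, smooth_predictions
from .metrics import aggregate_folds, compute_report
from .mstcn import MSTCNpp, build_mstcn_pp, subsample_frames, train
from .pose import preprocess_hand_track, preprocess_tool_track, tracks_to_features
from .simulate import VideoRecord
from .types import (
    FeatureSequence,
    LabelSequence,
    MetricsReport,
    ModelConfig,
    PreprocessConfig,
    ValidationError,
)


@dataclass(frozen=True)
class FoldSpec:
    """One LOUO fold: a validation surgeon, a test surgeon, the rest train."""

    val_surgeon: str
    test_surgeon: str
    train_surgeons: frozenset

    def __post_init__(self):
        if self.val_surgeon == self.test_surgeon:
            raise ValidationError("validation and test surgeon must differ")
        if not self.train_surgeons:
            raise ValidationError("training surgeon set must be non-empty")


def make_louo_folds(surgeons: Sequence[str]) -> list[FoldSpec]:
    """All ordered (validation, test) surgeon pairs, sorted."""
    ids = list(surgeons)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate surgeon ids")
    if len(ids) < 3:
        raise ValidationError("need >= 3 surgeons (otherwise no training data)")
    ordered = sorted(ids)
    return [FoldSpec(v, t, frozenset(s for s in ordered if s not in (v, t)))
            for v in ordered for t in ordered if v != t]


# ---------------------------------------------------------------- features

@dataclass
class ExperimentVideo:
    """A video with per-modality features ready for model consumption."""

    video_id: str
    surgeon: str
    features: dict  # modality -> FeatureSequence
    labels: LabelSequence


def prepare_video(record: VideoRecord,
                  preprocess_cfg: Optional[PreprocessConfig] = None
                  ) -> ExperimentVideo:
    """Run the pose cleaning chains and flatten all modalities to features."""
    if preprocess_cfg is None:
        preprocess_cfg = PreprocessConfig()
    tools = {tid: preprocess_tool_track(tr, preprocess_cfg)
             for tid, tr in record.tools.items()}
    hands = preprocess_hand_track(record.hands, preprocess_cfg)
    return ExperimentVideo(
        video_id=record.video_id,
        surgeon=record.surgeon,
        features={
            "tools": tracks_to_features(tools=tools, modality="tools"),
            "hands": tracks_to_features(hands=hands, modality="hands"),
            "video": record.video_features,
        },
        labels=record.labels,
    )


def prepare_dataset(records: Sequence[VideoRecord],
                    preprocess_cfg: Optional[PreprocessConfig] = None
                    ) -> list[ExperimentVideo]:
    return [prepare_video(r, preprocess_cfg) for r in records]


# ---------------------------------------------------------------- experiment

def _combo_key(combo: Sequence[str]) -> str:
    return "+".join(sorted(combo))


def _model_inputs(video: ExperimentVideo, key: str) -> FeatureSequence:
    if key.startswith("concat:"):
        mods = key[len("concat:"):].split("+")
        return concat_modalities([video.features[m] for m in mods])
    return video.features[key]


def _derive_seed(base_seed: int, fold_idx: int, key_idx: int) -> int:
    ss = np.random.SeedSequence([base_seed, fold_idx, key_idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _pose_entry_rows(video: ExperimentVideo, key: str) -> np.ndarray:
    """Channel indices of pose coordinate/quaternion entries for a model key.

    Validity flags and video-embedding channels are excluded: noise
    augmentation perturbs measured pose values only.
    """
    mods = key[len("concat:"):].split("+") if key.startswith("concat:") else [key]
    rows: list[int] = []
    off = 0
    for m in mods:
        d = video.features[m].dim
        if m == "hands":
            rows.extend(range(off, off + d - 2))  # 126 coordinates, skip flags
        elif m == "tools":
            for t in range(d // 8):  # per tool: 3 pos + 4 quat, skip flag
                rows.extend(range(off + 8 * t, off + 8 * t + 7))
        off += d
    return np.asarray(rows, dtype=int)


def _make_pose_noise_augment(rows: np.ndarray, sigma: float):
    """Per-step additive Gaussian noise on pose entries (training only)."""
    if sigma <= 0 or rows.size == 0:
        return None

    def augment(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        x = x.copy()
        x[rows] += rng.normal(0.0, sigma,
                              (rows.size, x.shape[1])).astype(np.float32)
        return x

    return augment


def run_experiment(videos: Sequence[ExperimentVideo],
                   combos: Sequence[Sequence[str]] = (("hands", "tools", "video"),),
                   model_cfgs: Optional[Mapping[str, ModelConfig]] = None,
                   min_run: int = 3,
                   seed: int = 0,
                   folds: Optional[Sequence[FoldSpec]] = None,
                   methods: Sequence[str] = ("straightforward", "ensemble"),
                   pose_noise_sigma: float = 0.0,
                   ) -> dict:
    """Train and evaluate the full LOUO x modality-combination matrix.

    ``model_cfgs`` maps a model key — a single modality name or
    ``'concat:<m1+m2+...>'`` — to its hyper-parameters (hyper-parameters are
    fixed per key across folds); missing keys fall back to ``ModelConfig()``.
    ``pose_noise_sigma`` enables training-time noise augmentation of pose
    feature entries (tool positions/quaternions and hand joints; validity
    flags and video embeddings untouched) — the regularizer that stops pose
    branches from memorizing surgeon-specific absolute positions.  Returns
    aggregated mean/std per (combo, method) plus the per-(video, fold)
    values needed for paired significance testing.  Fully seeded.
    """
    if not videos:
        raise ValidationError("empty dataset")
    model_cfgs = dict(model_cfgs or {})
    surgeons = sorted({v.surgeon for v in videos})
    if folds is None:
        folds = make_louo_folds(surgeons)

    methods = tuple(methods)
    if not methods or any(m not in ("straightforward", "ensemble") for m in methods):
        raise ValidationError(f"invalid methods {methods!r}")
    combos = [tuple(sorted(c)) for c in combos]
    all_modalities = sorted({m for c in combos for m in c})
    for v in videos:
        missing = [m for m in all_modalities if m not in v.features]
        if missing:
            raise ValidationError(f"video {v.video_id} missing modalities {missing}")
    # singles are needed as combos of their own or as ensemble constituents
    needed = {m for c in combos if len(c) == 1 for m in c}
    if "ensemble" in methods:
        needed.update(m for c in combos for m in c)
    model_keys = sorted(needed)
    for c in combos:
        if len(c) > 1:
            model_keys.append("concat:" + "+".join(c))

    results = {_combo_key(c): {method: [] for method in methods}
               for c in combos}
    paired: list[dict] = []

    for fold_idx, fold in enumerate(folds):
        train_videos = [v for v in videos if v.surgeon in fold.train_surgeons]
        val_videos = [v for v in videos if v.surgeon == fold.val_surgeon]
        test_videos = [v for v in videos if v.surgeon == fold.test_surgeon]
        if not test_videos:
            raise ValidationError(f"fold {fold_idx}: no test videos")

        models: dict[str, MSTCNpp] = {}
        for key_idx, key in enumerate(model_keys):
            cfg = model_cfgs.get(key, ModelConfig())
            cfg = replace(cfg, seed=_derive_seed(seed, fold_idx, key_idx))
            input_dim = _model_inputs(videos[0], key).dim
            model = build_mstcn_pp(cfg, input_dim, videos[0].labels.n_classes)
            augment = _make_pose_noise_augment(
                _pose_entry_rows(videos[0], key), pose_noise_sigma)
            train(model,
                  [( _model_inputs(v, key), v.labels) for v in train_videos],
                  [( _model_inputs(v, key), v.labels) for v in val_videos],
                  cfg, augment=augment)
            models[key] = model

        for combo in combos:
            ckey = _combo_key(combo)
            sf_key = combo[0] if len(combo) == 1 else "concat:" + "+".join(combo)
            member_keys = list(combo) + ([sf_key] if len(combo) > 1 else []) \
                if "ensemble" in methods else [sf_key]
            per_video = {method: [] for method in methods}
            for v in test_videos:
                stride = models[sf_key].cfg.stride
                gt = subsample_frames(v.labels, stride)
                logits = {k: models[k].predict_logits(
                    subsample_frames(_model_inputs(v, k), models[k].cfg.stride))
                    for k in member_keys}
                predictions = {}
                if "straightforward" in methods:
                    predictions["straightforward"] = logits[sf_key].argmax_labels(
                        v.labels.vocabulary, v.labels.fps)
                if "ensemble" in methods:
                    members = [logits[k] for k in member_keys]
                    if len(members) == 1:
                        predictions["ensemble"] = logits[sf_key].argmax_labels(
                            v.labels.vocabulary, v.labels.fps)
                    else:
                        predictions["ensemble"] = smooth_predictions(
                            average_logits(members).argmax_labels(
                                v.labels.vocabulary, v.labels.fps), min_run)
                for method, pred in predictions.items():
                    report = compute_report(pred, gt)
                    per_video[method].append(report)
                    paired.append({
                        "fold": fold_idx, "video_id": v.video_id,
                        "combo": ckey, "method": method,
                        **{m: getattr(report, m)
                           for m in MetricsReport.METRIC_FIELDS},
                    })
            for method in methods:
                reports = per_video[method]
                fold_report = MetricsReport(**{
                    m: float(np.mean([getattr(r, m) for r in reports]))
                    for m in MetricsReport.METRIC_FIELDS})
                results[_combo_key(combo)][method].append(fold_report)

    summary = {ckey: {method: aggregate_folds(rep_list)
                      for method, rep_list in methods.items()}
               for ckey, methods in results.items()}
    return {
        "folds": [{"val": f.val_surgeon, "test": f.test_surgeon} for f in folds],
        "summary": summary,
        "per_fold": {ckey: {method: [r.as_dict() for r in rep_list]
                            for method, rep_list in methods.items()}
                     for ckey, methods in results.items()},
        "paired": paired,
        "seed": seed,
    }


def paired_metric_values(report: dict, combo_a: str, method_a: str,
                         combo_b: str, method_b: str, metric: str
                         ) -> tuple[list[float], list[float]]:
    """Align per-(video, fold) metric values of two runs for paired testing."""
    def collect(combo, method):
        return {(r["fold"], r["video_id"]): r[metric]
                for r in report["paired"]
                if r["combo"] == combo and r["method"] == method}

    a, b = collect(combo_a, method_a), collect(combo_b, method_b)
    keys = sorted(set(a) & set(b))
    if not keys:
        raise ValidationError("no overlapping (fold, video) pairs")
    return [a[k] for k in keys], [b[k] for k in keys]


__all__ = [
    "FoldSpec", "make_louo_folds", "ExperimentVideo",
    "prepare_video", "prepare_dataset", "run_experiment",
    "paired_metric_values",
]
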