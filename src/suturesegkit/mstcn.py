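"""MS-TCN++ temporal segmentation model.

A multi-stage temporal convolutional network: a prediction-generation stage
of dual-dilated residual layers (each layer sees both a short and a long
dilation, 2^l and 2^(L-1-l)) followed by S-1 refinement stages that consume
the previous stage's class probabilities through single-dilation residual
layers.  Every stage emits frame-wise logits; training sums a
cross-entropy + truncated-MSE smoothing loss over the stages, which
penalizes over-segmentation.

The implementation is self-contained numpy (see :mod:`suturesegkit.autograd`)
so it runs and trains anywhere, CPU-only.
"""
from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from . import autograd as ag
from .types import (
    FeatureSequence,
    LabelSequence,
    LogitSequence,
    ModelConfig,
    ValidationError,
)


def _init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class MSTCNpp:
    """Parameter container and forward pass for the multi-stage TCN."""

    def __init__(self, cfg: ModelConfig, input_dim: int, n_classes: int):
        if input_dim < 1 or n_classes < 1:
            raise ValidationError("input_dim and n_classes must be >= 1")
        self.cfg = cfg
        self.input_dim = input_dim
        self.n_classes = n_classes
        rng = np.random.default_rng(cfg.seed)
        W, L, S, C = cfg.hidden_width, cfg.L, cfg.S, n_classes

        P = {}
        if cfg.input_batchnorm:
            P["bn_gamma"] = np.ones(input_dim, dtype=np.float32)
            P["bn_beta"] = np.zeros(input_dim, dtype=np.float32)
        P["pg_in_W"] = _init(rng, (W, input_dim), input_dim)
        P["pg_in_b"] = np.zeros(W, dtype=np.float32)
        for l in range(L):
            P[f"pg{l}_c1_W"] = _init(rng, (W, W, 3), 3 * W)
            P[f"pg{l}_c1_b"] = np.zeros(W, dtype=np.float32)
            P[f"pg{l}_c2_W"] = _init(rng, (W, W, 3), 3 * W)
            P[f"pg{l}_c2_b"] = np.zeros(W, dtype=np.float32)
            P[f"pg{l}_fuse_W"] = _init(rng, (W, 2 * W), 2 * W)
            P[f"pg{l}_fuse_b"] = np.zeros(W, dtype=np.float32)
        P["pg_head_W"] = _init(rng, (C, W), W)
        P["pg_head_b"] = np.zeros(C, dtype=np.float32)
        for s in range(1, S):
            P[f"r{s}_in_W"] = _init(rng, (W, C), C)
            P[f"r{s}_in_b"] = np.zeros(W, dtype=np.float32)
            for l in range(L):
                P[f"r{s}{l}_conv_W"] = _init(rng, (W, W, 3), 3 * W)
                P[f"r{s}{l}_conv_b"] = np.zeros(W, dtype=np.float32)
                P[f"r{s}{l}_px_W"] = _init(rng, (W, W), W)
                P[f"r{s}{l}_px_b"] = np.zeros(W, dtype=np.float32)
            P[f"r{s}_head_W"] = _init(rng, (C, W), W)
            P[f"r{s}_head_b"] = np.zeros(C, dtype=np.float32)
        self.params: dict[str, ag.Tensor] = {k: ag.parameter(v) for k, v in P.items()}
        self.bn_running_mean = np.zeros(input_dim, dtype=np.float64)
        self.bn_running_var = np.ones(input_dim, dtype=np.float64)

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> list[ag.Tensor]:
        return list(self.params.values())

    def get_state(self) -> dict:
        return {
            "params": {k: v.data.copy() for k, v in self.params.items()},
            "bn_running_mean": self.bn_running_mean.copy(),
            "bn_running_var": self.bn_running_var.copy(),
        }

    def set_state(self, state: dict) -> None:
        for k, v in state["params"].items():
            self.params[k].data = v.copy()
        self.bn_running_mean = state["bn_running_mean"].copy()
        self.bn_running_var = state["bn_running_var"].copy()

    # -- forward ------------------------------------------------------------

    def forward_tensors(self, x: np.ndarray, training: bool = False,
                        rng: Optional[np.random.Generator] = None,
                        ) -> list[ag.Tensor]:
        """Run all stages on a (D, T) array, returning per-stage (C, T) logits."""
        if x.shape[0] != self.input_dim:
            raise ValidationError(
                f"feature dim {x.shape[0]} != model input_dim {self.input_dim}")
        cfg = self.cfg
        P = self.params
        if rng is None:
            rng = np.random.default_rng(0)
        h = ag.Tensor(x)
        if cfg.input_batchnorm:
            h = ag.batchnorm_channels(h, P["bn_gamma"], P["bn_beta"],
                                      self.bn_running_mean, self.bn_running_var,
                                      training)
        h = ag.conv1x1(h, P["pg_in_W"], P["pg_in_b"])
        for l in range(cfg.L):
            c1 = ag.conv1d_k3(h, P[f"pg{l}_c1_W"], P[f"pg{l}_c1_b"], 2 ** l)
            c2 = ag.conv1d_k3(h, P[f"pg{l}_c2_W"], P[f"pg{l}_c2_b"],
                              2 ** (cfg.L - 1 - l))
            z = ag.concat_channels([c1, c2])
            z = ag.conv1x1(z, P[f"pg{l}_fuse_W"], P[f"pg{l}_fuse_b"])
            z = ag.relu(z)
            z = ag.dropout(z, cfg.dropout, rng, training)
            h = ag.add(h, z)
        logits = [ag.conv1x1(h, P["pg_head_W"], P["pg_head_b"])]
        for s in range(1, cfg.S):
            h = ag.softmax_channels(logits[-1])
            h = ag.conv1x1(h, P[f"r{s}_in_W"], P[f"r{s}_in_b"])
            for l in range(cfg.L):
                z = ag.conv1d_k3(h, P[f"r{s}{l}_conv_W"], P[f"r{s}{l}_conv_b"], 2 ** l)
                z = ag.relu(z)
                z = ag.conv1x1(z, P[f"r{s}{l}_px_W"], P[f"r{s}{l}_px_b"])
                z = ag.dropout(z, cfg.dropout, rng, training)
                h = ag.add(h, z)
            logits.append(ag.conv1x1(h, P[f"r{s}_head_W"], P[f"r{s}_head_b"]))
        return logits

    def forward(self, features: FeatureSequence) -> list[LogitSequence]:
        """Evaluation-mode forward: one LogitSequence per stage, deterministic."""
        outs = self.forward_tensors(features.values.T.astype(np.float32),
                                    training=False)
        return [LogitSequence(o.data.T.astype(np.float64), features.stride)
                for o in outs]

    def predict_logits(self, features: FeatureSequence) -> LogitSequence:
        """Final-stage logits (the model's prediction output)."""
        return self.forward(features)[-1]

    @property
    def receptive_field_radius(self) -> int:
        """Frames on each side that can influence a frame's final logits."""
        refine = sum(2 ** l for l in range(self.cfg.L))
        pg = sum(max(2 ** l, 2 ** (self.cfg.L - 1 - l)) for l in range(self.cfg.L))
        return pg + (self.cfg.S - 1) * refine


def build_mstcn_pp(cfg: ModelConfig, input_dim: int, n_classes: int) -> MSTCNpp:
    """Construct an MS-TCN++ with freshly initialized (seeded) parameters."""
    return MSTCNpp(cfg, input_dim, n_classes)


# --------------------------------------------------------------------- loss

def segmentation_loss(stage_logits: Sequence[LogitSequence],
                      labels: LabelSequence,
                      cfg: Optional[ModelConfig] = None) -> float:
    """Multi-stage loss: sum over stages of CE + lambda * truncated MSE.

    The truncated MSE averages ``min(tau, |log p_t,c - log p_{t-1,c}|)^2``
    over frames t >= 1 and classes, discouraging frame-to-frame probability
    jumps (over-segmentation) while the clip at tau keeps genuine gesture
    boundaries from dominating.
    """
    if cfg is None:
        cfg = ModelConfig()
    total = 0.0
    y = labels.labels
    for lg in stage_logits:
        if lg.n_frames != len(labels):
            raise ValidationError(
                f"stage length {lg.n_frames} != label length {len(labels)}")
        t = ag.mstcn_stage_loss(ag.Tensor(lg.values.T), y,
                                cfg.lambda_smooth, cfg.tau)
        total += float(t.data)
    return total


# --------------------------------------------------------------- subsampling

def subsample_frames(seq: Union[FeatureSequence, LabelSequence, LogitSequence],
                     stride: int):
    """Keep frames 0, stride, 2*stride, ...; the stride is recorded so
    predictions can later be expanded back to the source frame grid."""
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    if stride == 1:
        return seq
    if isinstance(seq, FeatureSequence):
        return FeatureSequence(seq.values[::stride], seq.modality,
                               seq.stride * stride)
    if isinstance(seq, LabelSequence):
        return LabelSequence(seq.labels[::stride], seq.vocabulary, seq.fps)
    if isinstance(seq, LogitSequence):
        return LogitSequence(seq.values[::stride], seq.stride * stride)
    raise TypeError(f"unsupported sequence type {type(seq)!r}")


def upsample_predictions(seq: Union[LabelSequence, LogitSequence],
                         stride: int, original_length: int):
    """Inverse of :func:`subsample_frames`: repeat each frame ``stride``
    times and truncate to the original length."""
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    if isinstance(seq, LabelSequence):
        values = np.repeat(seq.labels, stride)[:original_length]
        return LabelSequence(values, seq.vocabulary, seq.fps)
    if isinstance(seq, LogitSequence):
        values = np.repeat(seq.values, stride, axis=0)[:original_length]
        return LogitSequence(values, max(1, seq.stride // stride))
    raise TypeError(f"unsupported sequence type {type(seq)!r}")


# ------------------------------------------------------------------ training

@dataclass
class TrainLog:
    """Per-epoch training record plus the selected best epoch."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = -1.0


def _frame_accuracy(model: MSTCNpp, videos) -> float:
    correct = total = 0
    for feats, labels in videos:
        pred = np.argmax(model.predict_logits(feats).values, axis=1)
        correct += int((pred == labels.labels).sum())
        total += len(labels)
    return 100.0 * correct / max(total, 1)


def train(model: MSTCNpp,
          train_videos: Sequence[tuple[FeatureSequence, LabelSequence]],
          val_videos: Sequence[tuple[FeatureSequence, LabelSequence]],
          cfg: Optional[ModelConfig] = None,
          augment=None) -> TrainLog:
    """Train with Adam, one full video per optimization step.

    Subsamples inputs by ``cfg.stride`` first, early-stops on validation
    frame accuracy with ``cfg.patience`` non-improving epochs, restores the
    best-validation parameters, and is deterministic given ``cfg.seed``.

    ``augment``, if given, is a callable ``(x, rng) -> x`` applied to each
    training step's channel-major (D, T) float32 input — the hook for
    training-time augmentation such as per-entry pose noise or whole-video
    flips expressed in feature space.  Validation inputs are never
    augmented.
    """
    if cfg is None:
        cfg = model.cfg
    if len(train_videos) == 0:
        raise ValidationError("training set must contain at least one video")

    def prep(videos):
        return [(subsample_frames(f, cfg.stride), subsample_frames(y, cfg.stride))
                for f, y in videos]

    train_set = prep(train_videos)
    val_set = prep(val_videos)
    rng = np.random.default_rng(cfg.seed)
    opt = ag.Adam(model.parameters(), lr=cfg.lr)
    log = TrainLog()
    best_state = model.get_state()
    bad_epochs = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_set))
        losses = []
        for i in order:
            feats, labels = train_set[i]
            opt.zero_grad()
            x = feats.values.T.astype(np.float32)
            if augment is not None:
                x = augment(x, rng)
            stage_logits = model.forward_tensors(x, training=True, rng=rng)
            parts = [ag.mstcn_stage_loss(lg, labels.labels,
                                         cfg.lambda_smooth, cfg.tau)
                     for lg in stage_logits]
            loss = ag.sum_scalars(parts)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, video index {int(i)}: "
                    f"{float(loss.data)!r} (lr={cfg.lr})")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_acc = _frame_accuracy(model, val_set) if val_set else -float(np.mean(losses))
        log.epochs.append({"epoch": epoch,
                           "train_loss": float(np.mean(losses)),
                           "val_accuracy": float(val_acc)})
        if val_acc > log.best_val_accuracy:
            log.best_val_accuracy = float(val_acc)
            log.best_epoch = epoch
            best_state = model.get_state()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > cfg.patience:
                break
    model.set_state(best_state)
    return log


# --------------------------------------------------------------- checkpoints

def save_checkpoint(model: MSTCNpp, path: str,
                    vocabulary: Optional[Sequence[str]] = None) -> None:
    """Write a checkpoint: JSON header at ``path``, arrays at ``path.npz``."""
    header = {
        "config": asdict(model.cfg),
        "input_dim": model.input_dim,
        "n_classes": model.n_classes,
        "vocabulary": list(vocabulary) if vocabulary is not None else None,
        "arrays": str(path) + ".npz",
    }
    with open(path, "w") as fh:
        json.dump(header, fh, indent=2)
    state = model.get_state()
    arrays = {f"param/{k}": v for k, v in state["params"].items()}
    arrays["bn_running_mean"] = state["bn_running_mean"]
    arrays["bn_running_var"] = state["bn_running_var"]
    np.savez(str(path) + ".npz", **arrays)


def load_checkpoint(path: str) -> tuple[MSTCNpp, Optional[list[str]]]:
    with open(path) as fh:
        header = json.load(fh)
    cfg = ModelConfig(**header["config"])
    model = MSTCNpp(cfg, header["input_dim"], header["n_classes"])
    with np.load(header["arrays"]) as data:
        state = {
            "params": {k[len("param/"):]: data[k] for k in data.files
                       if k.startswith("param/")},
            "bn_running_mean": data["bn_running_mean"],
            "bn_running_var": data["bn_running_var"],
        }
    model.set_state(state)
    return model, header["vocabulary"]


__all__ = [
    "MSTCNpp", "build_mstcn_pp", "segmentation_loss",
    "subsample_frames", "upsample_predictions",
    "TrainLog", "train", "save_checkpoint", "load_checkpoint",
]
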