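"""Shipped hyper-parameter presets and a small grid-search helper.

``PRODUCTION_CONFIGS`` holds per-modality-combination MS-TCN++ settings at
production scale (hidden width 128); they are the per-combination optima of
the L/S/learning-rate grid when tuned on real multi-surgeon footage.
``DESK_SCALE_CONFIG`` is the small configuration the synthetic recovery
study trains on one CPU core.

``grid_search`` re-runs that selection on any dataset: for each candidate
it trains on one fold's training surgeons and scores validation frame
accuracy, returning the best configuration.  It is compute-hungry by
design and not part of any default path.
"""
from __future__ import annotations

from dataclasses import replace
from itertools import product
from typing import Optional, Sequence

from .mstcn import build_mstcn_pp, train
from .types import ModelConfig

#: The L/S/lr grid explored when tuning.
GRID_L = (3, 5, 8, 12)
GRID_S = (2, 3, 5)
GRID_LR = (1e-3, 1e-4, 1e-5)

PRODUCTION_CONFIGS: dict[str, ModelConfig] = {
    "hands": ModelConfig(L=5, S=2, lr=1e-3, hidden_width=128, stride=2),
    "tools": ModelConfig(L=8, S=5, lr=1e-4, hidden_width=128, stride=2),
    "video": ModelConfig(L=8, S=3, lr=1e-3, hidden_width=128, stride=2),
    "concat:hands+tools": ModelConfig(L=8, S=5, lr=1e-4, hidden_width=128,
                                      stride=2),
    "concat:hands+video": ModelConfig(L=8, S=2, lr=1e-3, hidden_width=128,
                                      stride=2),
    "concat:tools+video": ModelConfig(L=8, S=5, lr=1e-3, hidden_width=128,
                                      stride=2),
    "concat:hands+tools+video": ModelConfig(L=8, S=2, lr=1e-3,
                                            hidden_width=128, stride=2),
}

DESK_SCALE_CONFIG = ModelConfig(L=5, S=2, lr=3e-3, hidden_width=32, stride=2,
                                epochs=8, patience=2)


def grid_search(train_videos, val_videos,
                base_cfg: Optional[ModelConfig] = None,
                grid_l: Sequence[int] = GRID_L,
                grid_s: Sequence[int] = GRID_S,
                grid_lr: Sequence[float] = GRID_LR,
                ) -> tuple[ModelConfig, list[dict]]:
    """Select (L, S, lr) by validation frame accuracy.

    Ties break toward the earlier (smaller) candidate, mirroring the
    preference for smaller models on small datasets.  Returns the winning
    config and the full trial log.
    """
    if base_cfg is None:
        base_cfg = ModelConfig()
    input_dim = train_videos[0][0].dim
    n_classes = train_videos[0][1].n_classes
    best_cfg, best_acc = None, -1.0
    log = []
    for L, S, lr in product(grid_l, grid_s, grid_lr):
        cfg = replace(base_cfg, L=L, S=S, lr=lr)
        model = build_mstcn_pp(cfg, input_dim, n_classes)
        result = train(model, train_videos, val_videos, cfg)
        log.append({"L": L, "S": S, "lr": lr,
                    "val_accuracy": result.best_val_accuracy})
        if result.best_val_accuracy > best_acc:
            best_cfg, best_acc = cfg, result.best_val_accuracy
    return best_cfg, log


__all__ = ["PRODUCTION_CONFIGS", "DESK_SCALE_CONFIG", "GRID_L", "GRID_S",
           "GRID_LR", "grid_search"]
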