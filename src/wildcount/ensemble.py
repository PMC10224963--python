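"""K-fold ensemble: train K base U-Nets and fuse their probability maps.

Each base model trains on K-1 folds and validates on the held-out fold, so
the members see different data subsets. At inference each member's map is
min-max rescaled to [0, 1] (only when its maximum exceeds a small gate,
0.05 by default — a map that weak carries no detection evidence) and the
rescaled maps are averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from wildcount.annotation import PatchPair, split_folds
from wildcount.model import ModelConfig, TrainConfig, train_base_model, predict_patch
from wildcount.nn import UNet

logger = logging.getLogger(__name__)


@dataclass
class EnsembleConfig:
    K: int = 10
    rescale_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if not 0 < self.rescale_threshold < 1:
            raise ValueError("rescale_threshold must lie in (0, 1)")


def train_ensemble(
    pairs: list[PatchPair],
    mconfig: ModelConfig,
    tconfig: TrainConfig,
    econfig: EnsembleConfig,
) -> tuple[list[UNet], list[pd.DataFrame], dict]:
    """Train K base models on a seeded K-fold split of ``pairs``.

    Model ``i`` is trained on every fold except ``i`` and validated on fold
    ``i``. Returns the models, their training histories, and the fold
    assignment (patch id -> fold).
    """
    ids = [p.patch_id for p in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("patch ids must be unique")
    folds = split_folds(ids, K=econfig.K, seed=econfig.seed)
    models, histories = [], []
    for k in range(econfig.K):
        train_k = [p for p in pairs if folds[p.patch_id] != k]
        val_k = [p for p in pairs if folds[p.patch_id] == k]
        tconfig_k = TrainConfig(**{**tconfig.__dict__, "seed": tconfig.seed + k})
        model, history = train_base_model(train_k, val_k, mconfig, tconfig_k)
        models.append(model)
        histories.append(history)
        logger.info(
            "fold %d/%d: best val loss %.4f",
            k + 1, econfig.K, history["val_loss"].min(),
        )
    return models, histories, folds


def normalize_probmap(p: np.ndarray, threshold: float = 0.05) -> np.ndarray:
    """Min-max rescale a probability map to [0, 1], gated on its maximum.

    Maps whose maximum does not exceed ``threshold`` are returned unchanged.
    A constant map above the gate (max = min > threshold) has an undefined
    rescale; it is returned as all-zeros with a warning, since a featureless
    map carries no detection evidence.
    """
    p = np.asarray(p, dtype=np.float32)
    pmax = float(p.max()) if p.size else 0.0
    if pmax <= threshold:
        return p.copy()
    pmin = float(p.min())
    if pmax == pmin:
        logger.warning(
            "normalize_probmap: constant map at %.3f above gate; zeroing", pmax
        )
        return np.zeros_like(p)
    return (p - pmin) / (pmax - pmin)


def fuse(maps: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of probability maps (call after normalization)."""
    if not maps:
        raise ValueError("at least one map is required")
    shapes = {m.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"maps have mismatched shapes: {shapes}")
    return np.mean(np.stack(maps), axis=0, dtype=np.float64).astype(np.float32)


class EnsemblePredictor:
    """Callable bundle of base models: patch -> fused probability map."""

    def __init__(self, models: list[UNet], econfig: EnsembleConfig | None = None):
        if not models:
            raise ValueError("at least one model is required")
        self.models = models
        self.econfig = econfig or EnsembleConfig(K=max(2, len(models)))

    def member_maps(self, image: np.ndarray) -> list[np.ndarray]:
        """Per-member normalized probability maps for one (bands, H, W) patch."""
        return [
            normalize_probmap(predict_patch(m, image),
                              self.econfig.rescale_threshold)
            for m in self.models
        ]

    def __call__(self, image: np.ndarray) -> np.ndarray:
        return fuse(self.member_maps(image))
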