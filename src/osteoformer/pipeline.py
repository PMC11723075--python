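"""Training/evaluation driver and the runnable ablation grids.

Thin functional layer over :class:`~osteoformer.model.BoneSegmenter`:
``train`` fits one configuration on a list of phantoms and returns a
``TrainRecord``; ``run_ablation`` sweeps a configuration grid (Mix-FFN
depth 1..5, first-stage resolution, decoder attention on/off) and tabulates
mean IoU / DSC on the test split.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .config import Hyperparams, ModelConfig
from .metrics import evaluate_set
from .model import BoneSegmenter, SegmentationNet
from .phantoms import DatasetSplit, ImageSample

__all__ = ["TrainRecord", "train", "predict", "train_and_score", "run_ablation",
           "mixffn_depth_grid", "resolution_grid", "attention_grid"]


@dataclass
class TrainRecord:
    losses: list[float]
    model: SegmentationNet
    config: ModelConfig
    hyperparams: Hyperparams
    val_ious: list[float] = field(default_factory=list)
    wall_time: float = 0.0


def _stack(samples: list[ImageSample]):
    X = np.stack([s.image for s in samples]).astype(np.float32)
    y = np.stack([s.mask for s in samples])
    return X, y


def _fit(config: ModelConfig, hp: Hyperparams, train_set, val_set=None,
         max_steps=None) -> BoneSegmenter:
    est = BoneSegmenter(config=config, batch_size=hp.batch_size, epochs=hp.epochs,
                        learning_rate=hp.learning_rate, seed=hp.seed,
                        deterministic=hp.deterministic, max_steps=max_steps)
    X, y = _stack(train_set)
    if val_set:
        Xv, yv = _stack(val_set)
        est.fit(X, y, X_val=Xv, y_val=yv)
    else:
        est.fit(X, y)
    return est


def train(config: ModelConfig, hp: Hyperparams, train_set: list[ImageSample],
          val_set: list[ImageSample] | None = None,
          max_steps: int | None = None) -> TrainRecord:
    """Optimise pixel-wise cross-entropy with Adam per the training protocol."""
    if not train_set:
        raise ValueError("train_set must be nonempty")
    t0 = time.perf_counter()
    est = _fit(config, hp, train_set, val_set, max_steps)
    return TrainRecord(losses=est.loss_history_, model=est.net_, config=est.config_,
                       hyperparams=hp, val_ious=est.val_iou_history_,
                       wall_time=time.perf_counter() - t0)


def predict(model: SegmentationNet, image: np.ndarray) -> np.ndarray:
    """Binary (S, S) mask for one (1, S, S) or (S, S) image."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = img[None]
    if img.ndim != 3 or img.shape[0] != 1 or img.shape[1] != img.shape[2]:
        raise ValueError(f"expected a (1, S, S) image, got shape {img.shape}")
    model.config.stage_sides(img.shape[-1])
    return model.predict_masks(img[None])[0]


def train_and_score(config: ModelConfig, hp: Hyperparams, train_set, test_set) -> float:
    """Train, then return mean test IoU (the cross-validation cell)."""
    record = train(config, hp, train_set)
    preds = record.model.predict_masks(_stack(test_set)[0][:, None])
    return evaluate_set(list(preds), [s.mask for s in test_set]).mean_iou


def run_ablation(grid: list[ModelConfig], hp: Hyperparams, data: DatasetSplit,
                 descriptors: list[str] | None = None) -> pd.DataFrame:
    """One row per configuration: descriptor, mean IoU, mean DSC on data.test."""
    if descriptors is None:
        descriptors = [c.name or f"config_{i}" for i, c in enumerate(grid)]
    rows = []
    Xt = np.stack([s.image for s in data.test]).astype(np.float32)
    gts = [s.mask for s in data.test]
    for desc, cfg in zip(descriptors, grid):
        try:
            record = train(cfg, hp, data.train, val_set=data.val or None)
            preds = list(record.model.predict_masks(Xt[:, None]))
            ev = evaluate_set(preds, gts)
            rows.append({"config": desc, "mean_iou": ev.mean_iou,
                         "mean_dsc": ev.mean_dsc, "error": ""})
        except Exception as exc:  # noqa: BLE001 - record and continue the grid
            rows.append({"config": desc, "mean_iou": np.nan,
                         "mean_dsc": np.nan, "error": str(exc)})
    return pd.DataFrame(rows)


def mixffn_depth_grid(base: ModelConfig) -> tuple[list[ModelConfig], list[str]]:
    """Mix-FFN convolution depth M = 1..5 (M = 1 is the SegFormer baseline)."""
    grid = [base.replace(mixffn_conv_layers=m, name=f"M={m}") for m in range(1, 6)]
    names = ["1 (SegFormer)"] + [str(m) for m in range(2, 6)]
    return grid, names


def resolution_grid(base: ModelConfig, input_side: int = 256
                    ) -> tuple[list[ModelConfig], list[str]]:
    """First-stage feature side in {S/4, S/2, S, 2S}; later stages halve."""
    grids, names = [], []
    for f0 in (Fraction(1, 4), Fraction(1, 2), Fraction(1), Fraction(2)):
        fr = tuple(float(f0 / 2 ** i) for i in range(4))
        side = int(input_side * f0)
        label = f"{side} x {side} [px]"
        if f0 == Fraction(1, 4):
            label += " (SegFormer)"
        grids.append(base.replace(stage_fractions=fr, name=label))
        names.append(label)
    return grids, names


def attention_grid(base: ModelConfig) -> tuple[list[ModelConfig], list[str]]:
    """FPN decoder with the per-level attention blocks removed vs present."""
    off = base.replace(decoder_kind="fpn", decoder_attention=False,
                       name="FPN-based model without Attention mechanism")
    on = base.replace(decoder_kind="fpn", decoder_attention=True,
                      name="FPN-based model")
    return [off, on], [off.name, on.name]
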