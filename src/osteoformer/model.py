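"""End-to-end segmentation network and its scikit-learn-style wrapper."""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator

from .config import ConfigurationError, Hyperparams, ModelConfig, preset
from .decoders import build_decoder
from .encoder import HierarchicalEncoder, count_parameters
from .metrics import confusion_counts, iou
from .nn import Adam, Module, Tensor, cross_entropy_logits

__all__ = ["SegmentationNet", "BoneSegmenter", "save_checkpoint", "load_checkpoint"]


class SegmentationNet(Module):
    """Hierarchical encoder plus a decoder head; (B, 1, S, S) -> (B, C, S, S)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng([seed, 4000037])
        self.config = config
        self.encoder = HierarchicalEncoder(config, rng)
        self.decoder = build_decoder(config, rng)

    def forward(self, x: Tensor) -> Tensor:
        levels = self.encoder(x)
        return self.decoder(levels, x.shape[-1])

    def logits(self, images: np.ndarray) -> np.ndarray:
        """Inference forward pass on a (B, 1, S, S) float array."""
        return self(Tensor(np.asarray(images, dtype=np.float32))).data

    def predict_masks(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel argmax over classes -> (B, S, S) uint8 masks."""
        return self.logits(images).argmax(axis=1).astype(np.uint8)

    @property
    def n_parameters(self) -> int:
        return count_parameters(self)


class BoneSegmenter(BaseEstimator):
    """Trainable bone segmenter with the fit/predict estimator interface.

    Parameters
    ----------
    config : ModelConfig, str or None
        Architecture; a preset name (e.g. ``"tiny_proposed"``) or a full
        ``ModelConfig``.  None selects ``tiny_proposed``.
    batch_size, epochs, learning_rate, seed, deterministic
        Training protocol (defaults: 4, 20, 1e-3 with Adam and pixel-wise
        cross-entropy over foreground/background).

    Attributes (after ``fit``)
    --------------------------
    net_ : SegmentationNet            the trained network
    config_ : ModelConfig             the resolved architecture
    loss_history_ : list[float]       mean training loss per epoch
    val_iou_history_ : list[float]    mean validation IoU per epoch (if given)
    n_steps_ : int                    optimizer steps taken
    """

    def __init__(self, config=None, batch_size: int = 4, epochs: int = 20,
                 learning_rate: float = 1e-3, seed: int = 0,
                 deterministic: bool = True, max_steps: int | None = None):
        self.config = config
        self.batch_size = batch_size
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed
        self.deterministic = deterministic
        self.max_steps = max_steps

    # -- helpers ---------------------------------------------------------
    def _resolve_config(self) -> ModelConfig:
        if self.config is None:
            return preset("tiny_proposed")
        if isinstance(self.config, str):
            return preset(self.config)
        return self.config

    @staticmethod
    def _check_xy(X, y=None):
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError(f"X must be (n, S, S) with square images, got {X.shape}")
        if y is None:
            return X, None
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError(f"y shape {y.shape} does not match X {X.shape}")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary masks")
        return X, y.astype(np.intp)

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train on images X (n, S, S) in [0, 1] and binary masks y."""
        X, y = self._check_xy(X, y)
        if len(X) == 0:
            raise ValueError("cannot fit on an empty training set")
        cfg = self._resolve_config()
        side = X.shape[-1]
        cfg.stage_sides(side)  # raises ConfigurationError before any step
        seed = self.seed if self.deterministic else np.random.SeedSequence().entropy % (2 ** 31)
        rng = np.random.default_rng([int(seed), 5000011])
        self.net_ = SegmentationNet(cfg, seed=int(seed))
        self.config_ = cfg
        opt = Adam(self.net_.parameters(), lr=self.learning_rate)
        self.loss_history_ = []
        self.val_iou_history_ = []
        self.n_steps_ = 0
        n = len(X)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                logits = self.net_(Tensor(X[idx][:, None]))
                loss = cross_entropy_logits(logits, y[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
                self.n_steps_ += 1
                if self.max_steps is not None and self.n_steps_ >= self.max_steps:
                    break
            self.loss_history_.append(float(np.mean(losses)))
            if X_val is not None and y_val is not None:
                self.val_iou_history_.append(self.score(X_val, y_val))
            if self.max_steps is not None and self.n_steps_ >= self.max_steps:
                break
        return self

    def predict(self, X) -> np.ndarray:
        """Binary masks (n, S, S) by per-pixel argmax."""
        if not hasattr(self, "net_"):
            raise RuntimeError("BoneSegmenter is not fitted")
        X, _ = self._check_xy(X)
        side = X.shape[-1]
        self.config_.stage_sides(side)
        return self.net_.predict_masks(X[:, None])

    def score(self, X, y) -> float:
        """Mean per-image IoU of predictions against masks y."""
        X, y = self._check_xy(X, y)
        preds = self.predict(X)
        return float(np.mean([iou(confusion_counts(p, g)) for p, g in zip(preds, y)]))


def save_checkpoint(net: SegmentationNet, path) -> None:
    """Serialise weights plus an embedded config copy to an .npz archive."""
    state = net.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(net.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> SegmentationNet:
    with np.load(path) as data:
        cfg = ModelConfig.from_dict(json.loads(bytes(data["__config__"]).decode()))
        net = SegmentationNet(cfg)
        net.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return net
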