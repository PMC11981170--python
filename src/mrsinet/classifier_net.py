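"""Densely connected 1D classifier stacked on the transform block.

A DenseNet-style network consumes the transform block's spectral output
(real/imaginary channels) and emits a glioma probability through a
sigmoid head.  Each dense layer concatenates all preceding feature maps
(pre-activation batch norm -> ReLU -> convolution); transition layers
compress channels by half and average-pool by two.  The combined model's
user-facing input is always the raw time-domain FID.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .errors import (ConfigurationError, DataError, DivergenceError,
                     InvalidArgumentError)
from .nn import autograd as ag
from .records import SplitArrays
from .transform_net import TrainHistory, TransformNet, TransformNetConfig, _as_batch

BCE_EPS = 1e-7


@dataclass
class ClassifierConfig:
    """DenseNet-1D shape and training hyperparameters.

    Training defaults (batch 200, learning rate 5e-5, 100 epochs, BCE)
    follow the full-scale regime; desk-scale runs override them.
    """

    dense_blocks: int = 3
    layers_per_block: int = 4
    growth_rate: int = 16
    kernel: int = 3
    init_channels: int = 32
    learning_rate: float = 5e-5
    batch_size: int = 200
    epochs: int = 100
    loss: str = "bce"
    head: str = "sigmoid"
    fine_tune_transform: bool = True
    transform_lr_scale: float = 0.1
    threshold: float = 0.5
    allow_imbalance: bool = False
    patience: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ConfigurationError("kernel must be a positive odd integer")
        if min(self.dense_blocks, self.layers_per_block, self.growth_rate,
               self.init_channels) < 1:
            raise ConfigurationError("architecture sizes must be positive")
        if self.loss != "bce" or self.head != "sigmoid":
            raise ConfigurationError(
                "binary classification requires BCE loss and a sigmoid head")
        if not 0 < self.threshold < 1:
            raise ConfigurationError("threshold must lie in (0, 1)")


def bce_loss(labels: np.ndarray, probabilities: np.ndarray,
             eps: float = BCE_EPS) -> float:
    """Mean binary cross-entropy with probabilities clipped to [eps, 1-eps]."""
    y = np.asarray(labels, dtype=np.float64)
    p = np.asarray(probabilities, dtype=np.float64)
    if y.shape != p.shape:
        raise InvalidArgumentError(f"shape mismatch {y.shape} vs {p.shape}")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise InvalidArgumentError("labels must be binary 0/1")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class _DenseLayer(nn.Module):
    def __init__(self, in_channels: int, growth: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        self.bn = nn.BatchNorm1d(in_channels)
        self.conv = nn.Conv1d(in_channels, growth, kernel, rng)

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        return self.conv(ag.relu(self.bn(x)))


class _Transition(nn.Module):
    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.bn = nn.BatchNorm1d(in_channels)
        self.conv = nn.Conv1d(in_channels, out_channels, 1, rng)

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        return ag.avg_pool1d(self.conv(ag.relu(self.bn(x))), 2)


class DenseNet1d(nn.Module):
    """The classifier block: dense blocks -> global pooling -> FC -> logit."""

    def __init__(self, config: ClassifierConfig, in_channels: int = 2,
                 seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.stem = nn.Conv1d(in_channels, config.init_channels,
                              config.kernel, rng)
        channels = config.init_channels
        self.layers: List[Tuple[str, nn.Module]] = []
        for b in range(config.dense_blocks):
            for l in range(config.layers_per_block):
                layer = _DenseLayer(channels, config.growth_rate,
                                    config.kernel, rng)
                name = f"block{b}_layer{l}"
                setattr(self, name, layer)
                self.layers.append((name, layer))
                channels += config.growth_rate
            if b < config.dense_blocks - 1:
                out_ch = max(1, channels // 2)  # 0.5 compression
                trans = _Transition(channels, out_ch, rng)
                name = f"transition{b}"
                setattr(self, name, trans)
                self.layers.append((name, trans))
                channels = out_ch
        self.final_bn = nn.BatchNorm1d(channels)
        self.head = nn.Linear(channels, 1, rng)
        self.out_channels = channels
        #: feature map of the final convolutional layer, kept for Grad-CAM
        self.last_conv_features: Optional[ag.Tensor] = None

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        h = self.stem(x)
        for name, layer in self.layers:
            if name.startswith("transition"):
                h = layer(h)
            else:
                new = layer(h)
                # the final dense layer's own output is the "last conv"
                # feature map Grad-CAM differentiates against
                self.last_conv_features = new
                new.retain_grad()
                h = ag.concat([h, new], axis=1)
        h = ag.relu(self.final_bn(h))
        pooled = ag.mean(h, axis=2)  # global average pooling
        return ag.reshape(self.head(pooled), (x.shape[0],))


class CombinedModel(nn.Module):
    """Transform block + DenseNet classifier; raw FID in, probability out."""

    def __init__(self, transform: TransformNet, config: ClassifierConfig,
                 seed: int = 0):
        super().__init__()
        self.transform = transform
        self.classifier = DenseNet1d(config, in_channels=2, seed=seed)
        self.config = config

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        spectra = self.transform(x)  # (B, n_points, 2)
        if not self.config.fine_tune_transform:
            spectra = ag.Tensor(spectra.data)  # detach: freeze transform
        return self.classifier(ag.transpose(spectra, (0, 2, 1)))


def build_combined(transform_ckpt, config: Optional[ClassifierConfig] = None,
                   transform_config: Optional[TransformNetConfig] = None,
                   seed: int = 0) -> CombinedModel:
    """Assemble the combined model from a pretrained transform block.

    ``transform_ckpt`` is either a TransformNet instance or a state dict
    to load into a freshly built one (``transform_config`` then gives its
    architecture).
    """
    config = config or ClassifierConfig()
    if isinstance(transform_ckpt, TransformNet):
        transform = transform_ckpt
    else:
        transform = TransformNet(transform_config or TransformNetConfig(),
                                 seed=seed)
        try:
            transform.load_state_dict(transform_ckpt)
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(
                f"transform checkpoint does not match configuration: {exc}")
    return CombinedModel(transform, config, seed=seed)


def predict(model: CombinedModel, fids, batch_size: int = 256) -> np.ndarray:
    """Glioma probabilities in [0, 1] for raw FIDs, (N,)."""
    batch = _as_batch(fids, model.transform.config.n_points)
    model.eval()
    out = []
    for start in range(0, len(batch), batch_size):
        logits = model(ag.Tensor(batch[start:start + batch_size]))
        out.append(1.0 / (1.0 + np.exp(-logits.data.astype(np.float64))))
    return np.concatenate(out)


def _check_balance(labels: np.ndarray, allow_imbalance: bool) -> None:
    labels = np.asarray(labels)
    frac_pos = labels.mean()
    if frac_pos in (0.0, 1.0):
        raise DataError("training data contains a single class")
    if not allow_imbalance and not 0.4 <= frac_pos <= 0.6:
        raise DataError(
            f"class imbalance {frac_pos:.2f} positive exceeds 60/40; "
            "set allow_imbalance to proceed")


def train_classifier(model: CombinedModel, train_split: SplitArrays,
                     val_split: SplitArrays,
                     config: Optional[ClassifierConfig] = None,
                     seed: int = 0,
                     ) -> Tuple[Dict[str, np.ndarray], TrainHistory]:
    """Train the combined stack with Adam on BCE; best-validation weights.

    The transform block is fine-tuned at a reduced learning rate by
    default; with ``fine_tune_transform=False`` its weights are bitwise
    unchanged.
    """
    config = config or model.config
    if train_split.labels is None or val_split.labels is None:
        raise DataError("labeled splits are required")
    if len(train_split) == 0 or len(val_split) == 0:
        raise DataError("empty training or validation split")
    _check_balance(train_split.labels, config.allow_imbalance)
    rng = np.random.default_rng(seed)
    groups: List[Tuple[List, float]] = [(model.classifier.parameters(), 1.0)]
    if config.fine_tune_transform:
        groups.append((model.transform.parameters(),
                       config.transform_lr_scale))
    opt = nn.Adam(groups, lr=config.learning_rate)
    history = TrainHistory(seed=seed)
    best_val = np.inf
    best_state = model.state_dict()
    x_all = train_split.fids.astype(np.float32)
    y_all = train_split.labels.astype(np.float32)
    t0 = time.perf_counter()
    since_best = 0
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(x_all))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model(ag.Tensor(x_all[idx]))
            loss = ag.bce_with_logits_loss(logits, y_all[idx])
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        probs = predict(model, val_split.fids)
        val = bce_loss(val_split.labels, probs)
        history.train_loss.append(float(np.mean(losses)))
        history.val_loss.append(val)
        if val < best_val:
            best_val = val
            best_state = model.state_dict()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if config.patience is not None and since_best >= config.patience:
                break
    history.wall_seconds = time.perf_counter() - t0
    model.load_state_dict(best_state)
    return best_state, history
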