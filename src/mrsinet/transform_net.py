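"""Domain-transformation network: raw 1024-point FID -> MR spectrum.

An AUTOMAP-inspired 1D instantiation: three fully connected layers with
hyperbolic-tangent activation learn the (phase-corrected) time-to-
frequency mapping, then two ReLU convolutional layers and a transposed
convolution denoise and sharpen the spectral estimate.  The real and
imaginary output channels are, by default, produced by two channel-wise
instances sharing the architecture and training loop; a single shared
network with 2-channel output is available as a configuration switch.

Trained with mean-squared-error loss and Adam on (augmented FID, clean
normalized spectrum) pairs from the simulator.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import nn
from .errors import (ConfigurationError, DataError, DivergenceError,
                     InvalidArgumentError)
from .metrics import mse as _mse_metric
from .nn import autograd as ag
from .records import FidRecord, SplitArrays


@dataclass
class TransformNetConfig:
    """Architecture and training hyperparameters of the transform block.

    Training defaults (batch 20, learning rate 5e-6, 200 epochs, MSE)
    suit the full-scale 40,000-example regime; desk-scale runs override
    them.
    """

    n_points: int = 1024
    fc_widths: Tuple[int, int, int] = (1024, 1024, 1024)
    conv_channels: Tuple[int, int] = (64, 64)
    conv_kernel: int = 5
    learning_rate: float = 5e-6
    batch_size: int = 20
    epochs: int = 200
    loss: str = "mse"
    shared_channels: bool = False
    patience: Optional[int] = None  # early stopping off by default

    def __post_init__(self) -> None:
        if len(self.fc_widths) != 3:
            raise ConfigurationError("exactly 3 fully connected layers required")
        if len(self.conv_channels) != 2:
            raise ConfigurationError("exactly 2 convolutional layers required")
        if self.conv_kernel % 2 == 0 or self.conv_kernel < 1:
            raise ConfigurationError("conv kernel must be a positive odd integer")
        if self.fc_widths[-1] != self.n_points:
            raise ConfigurationError(
                "last FC width must equal n_points (conv input length)")
        if self.loss != "mse":
            raise ConfigurationError("transform net trains with MSE loss")
        if min(self.fc_widths) < 1 or min(self.conv_channels) < 1:
            raise ConfigurationError("layer sizes must be positive")


@dataclass
class TrainHistory:
    """Per-epoch loss curves of one training run."""

    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    wall_seconds: float = 0.0
    seed: int = 0
    best_epoch: int = -1


class _ChannelNet(nn.Module):
    """FC(tanh) x3 -> Conv1d(ReLU) x2 -> ConvTranspose1d, one output channel."""

    def __init__(self, config: TransformNetConfig, out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        w1, w2, w3 = config.fc_widths
        self.fc1 = nn.Linear(2 * config.n_points, w1, rng)
        self.fc2 = nn.Linear(w1, w2, rng)
        self.fc3 = nn.Linear(w2, w3, rng)
        c1, c2 = config.conv_channels
        self.conv1 = nn.Conv1d(1, c1, config.conv_kernel, rng)
        self.conv2 = nn.Conv1d(c1, c2, config.conv_kernel, rng)
        self.deconv = nn.ConvTranspose1d(c2, out_channels, config.conv_kernel, rng)
        self.n_points = config.n_points

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        h = ag.tanh(self.fc1(x))
        h = ag.tanh(self.fc2(h))
        h = ag.tanh(self.fc3(h))
        h = ag.reshape(h, (x.shape[0], 1, self.n_points))
        h = ag.relu(self.conv1(h))
        h = ag.relu(self.conv2(h))
        return self.deconv(h)  # (B, out_channels, n_points)


class TransformNet(nn.Module):
    """The full transform block; input (B, n_points, 2), output the same."""

    def __init__(self, config: TransformNetConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        if config.shared_channels:
            self.shared = _ChannelNet(config, 2, rng)
        else:
            self.real_net = _ChannelNet(config, 1, rng)
            self.imag_net = _ChannelNet(config, 1, rng)

    def __call__(self, x: ag.Tensor) -> ag.Tensor:
        flat = ag.reshape(x, (x.shape[0], 2 * self.config.n_points))
        if self.config.shared_channels:
            out = self.shared(flat)
        else:
            out = ag.concat([self.real_net(flat), self.imag_net(flat)], axis=1)
        return ag.transpose(out, (0, 2, 1))  # (B, n_points, 2)

    def layer_types(self) -> List[str]:
        return ["FC", "FC", "FC", "Conv", "Conv", "Deconv"]


def build_transform_net(config: Optional[TransformNetConfig] = None,
                        seed: int = 0) -> TransformNet:
    """Construct the transform network with seed-deterministic weights."""
    return TransformNet(config or TransformNetConfig(), seed=seed)


def mse_loss(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared error over all spectra, points and channels."""
    return _mse_metric(y, y_hat)


def _as_batch(arr: np.ndarray, n_points: int) -> np.ndarray:
    arr = np.asarray(arr, dtype=np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1] != n_points or arr.shape[2] != 2:
        raise InvalidArgumentError(
            f"expected (N, {n_points}, 2) input, got {arr.shape}")
    return arr


def transform(model: TransformNet, fids, batch_size: int = 256) -> np.ndarray:
    """Predict normalized spectra for FIDs; returns (N, n_points, 2).

    Accepts an (N, n_points, 2) float array, a single (n_points, 2)
    array, or a FidRecord.
    """
    if isinstance(fids, FidRecord):
        fids = np.stack([fids.samples.real, fids.samples.imag], axis=-1)
    batch = _as_batch(fids, model.config.n_points)
    model.eval()
    outs = []
    for start in range(0, len(batch), batch_size):
        x = ag.Tensor(batch[start:start + batch_size])
        outs.append(model(x).data)
    # predictions live in the normalized target convention
    return np.clip(np.concatenate(outs, axis=0), 0.0, 1.0)


def _epoch_val_mse(model: TransformNet, split: SplitArrays,
                   batch_size: int) -> float:
    pred = transform(model, split.fids, batch_size=batch_size)
    return mse_loss(split.targets, pred)


def train_transform(model: TransformNet, train_split: SplitArrays,
                    val_split: SplitArrays,
                    config: Optional[TransformNetConfig] = None,
                    seed: int = 0,
                    ) -> Tuple[Dict[str, np.ndarray], TrainHistory]:
    """Train with Adam; returns (best-validation weights, history).

    Deterministic given the seed and data.  Raises
    :class:`DivergenceError` on a non-finite loss.
    """
    config = config or model.config
    if len(train_split) == 0 or len(val_split) == 0:
        raise DataError("empty training or validation split")
    rng = np.random.default_rng(seed)
    opt = nn.Adam([(model.parameters(), 1.0)], lr=config.learning_rate)
    history = TrainHistory(seed=seed)
    best_val = np.inf
    best_state: Dict[str, np.ndarray] = model.state_dict()
    t0 = time.perf_counter()
    x_all = train_split.fids.astype(np.float32)
    y_all = train_split.targets.astype(np.float32)
    since_best = 0
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(len(x_all))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            x = ag.Tensor(x_all[idx])
            pred = model(x)
            loss = ag.mse_loss(pred, y_all[idx])
            if not np.isfinite(loss.data):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}, "
                    f"step {start // config.batch_size}: {loss.data!r}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val = _epoch_val_mse(model, val_split, batch_size=256)
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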