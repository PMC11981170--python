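"""Network building blocks on top of the autograd engine."""

from __future__ import annotations

from typing import Dict, Iterator, List, Tuple

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Module:
    """Base class: parameter registration, mode flag, state dict."""

    def __init__(self) -> None:
        self._params: Dict[str, Tensor] = {}
        self._buffers: Dict[str, np.ndarray] = {}
        self._children: Dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(array, dtype=np.float32), requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, array: np.ndarray) -> np.ndarray:
        arr = np.asarray(array, dtype=np.float64)
        self._buffers[name] = arr
        return arr

    def parameters(self) -> List[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_state(self, prefix: str = "") -> Iterator[Tuple[str, np.ndarray, bool]]:
        for name, t in self._params.items():
            yield prefix + name, t.data, True
        for name, b in self._buffers.items():
            yield prefix + name, b, False
        for cname, child in self._children.items():
            yield from child.named_state(prefix + cname + ".")

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: arr.copy() for name, arr, _ in self.named_state()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = {name: (arr, is_param) for name, arr, is_param in self.named_state()}
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state dict mismatch: missing={sorted(missing)}, "
                           f"unexpected={sorted(extra)}")
        for name, (arr, _) in own.items():
            src = np.asarray(state[name])
            if src.shape != arr.shape:
                raise ValueError(f"{name}: shape {src.shape} != {arr.shape}")
            arr[...] = src

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (in_features + out_features))  # Glorot uniform
        self.weight = self.register_parameter(
            "weight", rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = self.register_parameter(
            "bias", rng.uniform(-0.01, 0.01, out_features))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.add(ag.matmul(x, self.weight), self.bias)


class Conv1d(Module):
    """Stride-1, same-padding 1D convolution (cross-correlation)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {kernel}")
        fan_in = in_channels * kernel
        bound = np.sqrt(2.0 / fan_in)  # He init for ReLU chains
        self.weight = self.register_parameter(
            "weight", rng.normal(0.0, bound, (out_channels, in_channels, kernel)))
        # small non-zero bias: avoids bias-dominated dead ReLU channels
        # while breaking exact zero-activation ties
        self.bias = self.register_parameter(
            "bias", rng.uniform(-0.01, 0.01, out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.conv1d(x, self.weight, self.bias)


class ConvTranspose1d(Module):
    """Stride-1 transposed convolution (adjoint of same-padding Conv1d)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {kernel}")
        fan_in = in_channels * kernel
        bound = np.sqrt(2.0 / fan_in)
        self.weight = self.register_parameter(
            "weight", rng.normal(0.0, bound, (in_channels, out_channels, kernel)))
        # small non-zero bias: avoids bias-dominated dead ReLU channels
        # while breaking exact zero-activation ties
        self.bias = self.register_parameter(
            "bias", rng.uniform(-0.01, 0.01, out_channels))

    def __call__(self, x: Tensor) -> Tensor:
        w = ag.flip(ag.transpose(self.weight, (1, 0, 2)), axis=2)
        return ag.conv1d(x, w, self.bias)


class BatchNorm1d(Module):
    def __init__(self, channels: int):
        super().__init__()
        self.gamma = self.register_parameter("gamma", np.ones(channels))
        self.beta = self.register_parameter("beta", np.zeros(channels))
        self.running_mean = self.register_buffer("running_mean", np.zeros(channels))
        self.running_var = self.register_buffer("running_var", np.ones(channels))

    def __call__(self, x: Tensor) -> Tensor:
        return ag.batch_norm1d(x, self.gamma, self.beta, self.running_mean,
                               self.running_var, training=self.training)


class Adam:
    """Adam optimizer with optional per-group learning-rate scaling."""

    def __init__(self, param_groups: List[Tuple[List[Tensor], float]],
                 lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.groups = param_groups
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p.data) for p in params]
                  for params, _ in param_groups]
        self.v = [[np.zeros_like(p.data) for p in params]
                  for params, _ in param_groups]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.beta1 ** self.t
        bc2 = 1.0 - self.beta2 ** self.t
        for gi, (params, scale) in enumerate(self.groups):
            lr = self.lr * scale
            for pi, p in enumerate(params):
                if p.grad is None:
                    continue
                g = p.grad
                m = self.m[gi][pi]
                v = self.v[gi][pi]
                m *= self.beta1
                m += (1 - self.beta1) * g
                v *= self.beta2
                v += (1 - self.beta2) * (g * g)
                p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for params, _ in self.groups:
            for p in params:
                p.grad = None
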