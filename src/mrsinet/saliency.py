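"""1D Grad-CAM saliency over the classifier's final convolutional layer.

For a class score s and final-layer feature maps A_k, the channel
weights are the spatial means alpha_k = mean_t ds/dA_k(t) and the map is
ReLU(sum_k alpha_k A_k), linearly interpolated to the spectral axis and
max-normalized.  For the healthy class the score is the negated glioma
logit, so both classes yield positive-evidence maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, InvalidArgumentError
from .nn import autograd as ag
from .records import FidRecord

#: Metabolite windows reported by default (ppm).
DEFAULT_REGIONS: Dict[str, Tuple[float, float]] = {
    "tCho": (3.1, 3.3),
    "NAA": (1.9, 2.1),
    "Glx/2-HG": (2.15, 2.35),
    "tCr": (2.95, 3.05),
}


@dataclass
class SaliencyMap:
    """Non-negative, max-normalized importance over the ppm axis."""

    importance: np.ndarray
    ppm_axis: np.ndarray
    target_class: str
    layer_name: str

    def __post_init__(self) -> None:
        if len(self.importance) != len(self.ppm_axis):
            raise InvalidArgumentError("importance / ppm axis length mismatch")


@dataclass
class RegionEntry:
    name: str
    ppm_lo: float
    ppm_hi: float
    mean_importance: float
    rank: int = 0


@dataclass
class RegionReport:
    """Mean saliency per named ppm window, ranked descending."""

    entries: List[RegionEntry] = field(default_factory=list)
    target_class: str = ""
    n_maps: int = 0

    def by_name(self, name: str) -> RegionEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def top(self) -> RegionEntry:
        return min(self.entries, key=lambda e: e.rank)

    def to_rows(self) -> List[Dict]:
        return [{"window_name": e.name, "ppm_lo": e.ppm_lo,
                 "ppm_hi": e.ppm_hi, "mean_importance": e.mean_importance,
                 "rank": e.rank} for e in self.entries]


def _resolve_attr(obj, dotted: str):
    for part in dotted.split("."):
        if not hasattr(obj, part):
            raise ConfigurationError(
                f"model has no feature attribute '{dotted}' — a model with "
                "at least one convolutional layer is required")
        obj = getattr(obj, part)
    return obj


def grad_cam(model, input_fid, target_class: str = "glioma",
             ppm_axis: Optional[np.ndarray] = None,
             layer_name: str = "classifier.last_conv_features") -> SaliencyMap:
    """Saliency map of one example for the glioma or healthy class.

    ``model`` maps a (1, n, 2) tensor to a (1,) logit and records its
    final convolutional feature map in the attribute named by
    ``layer_name`` during the forward pass.  Deterministic: repeated
    calls return identical maps.
    """
    if target_class not in ("glioma", "healthy"):
        raise InvalidArgumentError(
            f"target_class must be 'glioma' or 'healthy', got {target_class!r}")
    if isinstance(input_fid, FidRecord):
        ppm_axis = input_fid.grid.ppm_axis if ppm_axis is None else ppm_axis
        input_fid = np.stack([input_fid.samples.real,
                              input_fid.samples.imag], axis=-1)
    x = np.asarray(input_fid, dtype=np.float32)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[0] != 1:
        raise InvalidArgumentError("grad_cam expects a single example")
    if ppm_axis is None:
        raise InvalidArgumentError("a ppm axis is required")
    if hasattr(model, "eval"):
        model.eval()
    logits = model(ag.Tensor(x))
    features = _resolve_attr(model, layer_name)
    if features is None:
        raise ConfigurationError(
            f"'{layer_name}' was not populated by the forward pass")
    features.retain_grad()
    sign = 1.0 if target_class == "glioma" else -1.0
    logits.backward(np.full(logits.shape, sign, dtype=logits.data.dtype))
    if features.grad is None:
        raise ConfigurationError("no gradient reached the feature maps")
    grads = features.grad[0]          # (K, L')
    fmaps = features.data[0]          # (K, L')
    alphas = grads.mean(axis=1)       # spatial mean per channel
    cam = np.maximum((alphas[:, None] * fmaps).sum(axis=0), 0.0)
    n_out = len(ppm_axis)
    if len(cam) != n_out:
        src = np.linspace(0.0, 1.0, len(cam))
        dst = np.linspace(0.0, 1.0, n_out)
        cam = np.interp(dst, src, cam)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return SaliencyMap(importance=cam.astype(np.float64),
                       ppm_axis=np.asarray(ppm_axis, dtype=np.float64),
                       target_class=target_class, layer_name=layer_name)


def region_report(maps: Sequence[SaliencyMap],
                  windows: Optional[Dict[str, Tuple[float, float]]] = None,
                  ) -> RegionReport:
    """Mean importance per ppm window averaged over maps, ranked descending.

    Ties rank by window declaration order (stable sort).
    """
    maps = list(maps)
    if not maps:
        raise InvalidArgumentError("at least one saliency map is required")
    windows = windows or DEFAULT_REGIONS
    axis = maps[0].ppm_axis
    entries = []
    for name, (lo, hi) in windows.items():
        if lo > hi:
            raise InvalidArgumentError(f"window {name}: lo {lo} > hi {hi}")
        if lo < axis.min() or hi > axis.max():
            raise InvalidArgumentError(
                f"window {name} [{lo}, {hi}] outside ppm axis "
                f"[{axis.min():.2f}, {axis.max():.2f}]")
        mask = (axis >= lo) & (axis <= hi)
        vals = [float(m.importance[mask].mean()) for m in maps]
        entries.append(RegionEntry(name=name, ppm_lo=lo, ppm_hi=hi,
                                   mean_importance=float(np.mean(vals))))
    order = sorted(range(len(entries)),
                   key=lambda i: -entries[i].mean_importance)
    for rank, idx in enumerate(order, start=1):
        entries[idx].rank = rank
    return RegionReport(entries=entries,
                        target_class=maps[0].target_class, n_maps=len(maps))
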