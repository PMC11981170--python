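"""Reconstruction- and classification-quality metrics.

Reconstruction metrics (MSE/RMSE/PSNR/SSIM and the spectroscopic
creatine SNR) score predicted spectra against ground truth; the
classification metrics (ROC/AUC, confusion matrix) score the binary
glioma-vs-healthy output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import InvalidArgumentError
from .records import AcquisitionGrid, SpectrumRecord

#: 1D SSIM parameters (standard image-SSIM defaults adapted to spectra).
SSIM_WINDOW = 11
SSIM_SIGMA = 1.5
SSIM_K1 = 0.01
SSIM_K2 = 0.03

#: Spectroscopic SNR windows (ppm): creatine peak and signal-free baseline.
CREATINE_WINDOW_PPM = (2.9, 3.1)
BASELINE_WINDOW_PPM = (8.0, 9.0)


@dataclass
class ReconReport:
    """Batch reconstruction metrics, each as (mean, SD) over examples."""

    mse: Tuple[float, float]
    rmse: Tuple[float, float]
    psnr: Tuple[float, float]
    ssim: Tuple[float, float]
    snr_creatine: Optional[Tuple[float, float]] = None
    n: int = 0
    psnr_infinite: bool = False
    params: Dict = field(default_factory=lambda: {
        "ssim_window": SSIM_WINDOW, "ssim_sigma": SSIM_SIGMA,
        "ssim_k1": SSIM_K1, "ssim_k2": SSIM_K2, "psnr_max": 1.0})

    def to_dict(self) -> Dict:
        out = {"n": self.n, "psnr_infinite": self.psnr_infinite,
               "params": dict(self.params)}
        for name in ("mse", "rmse", "psnr", "ssim", "snr_creatine"):
            val = getattr(self, name)
            if val is not None:
                out[name] = {"mean": val[0], "sd": val[1]}
        return out


@dataclass
class RocReport:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_dict(self) -> Dict:
        return {"auc": self.auc, "fpr": self.fpr.tolist(),
                "tpr": self.tpr.tolist(),
                "thresholds": self.thresholds.tolist()}


@dataclass
class ConfusionReport:
    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    def percentages(self) -> Dict[str, float]:
        """Cell percentages of the total, rounded to 2 decimals."""
        return {k: round(100.0 * v / self.n, 2)
                for k, v in (("tp", self.tp), ("fn", self.fn),
                             ("fp", self.fp), ("tn", self.tn))}

    def to_dict(self) -> Dict:
        return {"tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
                "percent": self.percentages(),
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy}


def sensitivity_specificity_from_cells(tp: float, fn: float, fp: float,
                                       tn: float) -> Tuple[float, float]:
    """Sensitivity and specificity from (possibly fractional) cell counts.

    Accepts percentages of the total as well as raw counts, since both
    ratios are scale-invariant.
    """
    if min(tp, fn, fp, tn) < 0:
        raise InvalidArgumentError("confusion cells must be non-negative")
    return tp / (tp + fn), tn / (tn + fp)


def mse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared error over all points and channels."""
    y, y_hat = np.asarray(y, dtype=np.float64), np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise InvalidArgumentError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    return float(np.mean((y - y_hat) ** 2))


def per_example_mse(y: np.ndarray, y_hat: np.ndarray) -> np.ndarray:
    """(N,) MSE per example of (N, ...) batches."""
    y, y_hat = np.asarray(y, dtype=np.float64), np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise InvalidArgumentError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    return ((y - y_hat) ** 2).reshape(len(y), -1).mean(axis=1)


def psnr(y: np.ndarray, y_hat: np.ndarray, max_value: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB: 10*log10(max^2 / MSE).

    Spectra are [0, 1]-normalized, hence the default peak of 1.
    Returns ``inf`` when the reconstruction is exact.
    """
    err = mse(y, y_hat)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(max_value ** 2 / err))


def _gaussian_window(size: int, sigma: float) -> np.ndarray:
    x = np.arange(size) - (size - 1) / 2.0
    w = np.exp(-(x ** 2) / (2 * sigma ** 2))
    return w / w.sum()


def ssim_1d(y: np.ndarray, y_hat: np.ndarray,
            data_range: float = 1.0,
            window: int = SSIM_WINDOW, sigma: float = SSIM_SIGMA,
            k1: float = SSIM_K1, k2: float = SSIM_K2) -> float:
    """Structural similarity of two 1D signals (or (n, C) channel stacks).

    Sliding Gaussian-weighted window (size 11, sigma 1.5), constants
    C1 = (k1*L)^2, C2 = (k2*L)^2 with dynamic range L, averaged over all
    window positions (valid mode) and channels.
    """
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise InvalidArgumentError(f"shape mismatch {y.shape} vs {y_hat.shape}")
    if y.ndim == 1:
        y, y_hat = y[:, None], y_hat[:, None]
    if y.shape[0] < window:
        raise InvalidArgumentError(
            f"signal length {y.shape[0]} shorter than SSIM window {window}")
    w = _gaussian_window(window, sigma)
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    vals = []
    for ch in range(y.shape[1]):
        a, b = y[:, ch], y_hat[:, ch]
        mu_a = np.convolve(a, w, mode="valid")
        mu_b = np.convolve(b, w, mode="valid")
        mu_aa = np.convolve(a * a, w, mode="valid")
        mu_bb = np.convolve(b * b, w, mode="valid")
        mu_ab = np.convolve(a * b, w, mode="valid")
        # sample-style (unbiased-equivalent) moments as in the reference SSIM
        cov_norm = 1.0  # Gaussian weights sum to 1; population moments
        var_a = cov_norm * (mu_aa - mu_a * mu_a)
        var_b = cov_norm * (mu_bb - mu_b * mu_b)
        cov = cov_norm * (mu_ab - mu_a * mu_b)
        num = (2 * mu_a * mu_b + c1) * (2 * cov + c2)
        den = (mu_a ** 2 + mu_b ** 2 + c1) * (var_a + var_b + c2)
        vals.append(np.mean(num / den))
    return float(np.mean(vals))


def snr_creatine(spectrum: SpectrumRecord | np.ndarray,
                 grid: Optional[AcquisitionGrid] = None,
                 ppm_axis: Optional[np.ndarray] = None) -> float:
    """Spectroscopic SNR: creatine peak-to-peak over 8-9 ppm baseline SD.

    The signal is the max-min of the real channel within 2.9-3.1 ppm;
    the noise is the standard deviation of the real channel within the
    signal-free 8.0-9.0 ppm window.  Returns ``inf`` when the baseline
    is exactly flat.
    """
    if isinstance(spectrum, SpectrumRecord):
        real = spectrum.real_part
        axis = spectrum.ppm_axis
    else:
        real = np.asarray(spectrum, dtype=np.float64)
        if real.ndim == 2:
            real = real[:, 0]
        axis = grid.ppm_axis if grid is not None else ppm_axis
        if axis is None:
            raise InvalidArgumentError("a ppm axis is required for raw arrays")
    cr = (axis >= CREATINE_WINDOW_PPM[0]) & (axis <= CREATINE_WINDOW_PPM[1])
    base = (axis >= BASELINE_WINDOW_PPM[0]) & (axis <= BASELINE_WINDOW_PPM[1])
    if not cr.any() or not base.any():
        raise InvalidArgumentError(
            "ppm axis does not cover the creatine and baseline windows")
    signal = float(real[cr].max() - real[cr].min())
    noise = float(real[base].std())
    if noise == 0:
        return float("inf")
    return signal / noise


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> RocReport:
    """ROC curve over unique score thresholds plus trapezoidal AUC.

    Ties are handled by simultaneous threshold crossing, equivalent to
    mid-rank AUC.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise InvalidArgumentError("labels and scores must be equal-length 1D")
    if not set(np.unique(labels)) <= {0, 1}:
        raise InvalidArgumentError("labels must be binary 0/1")
    if len(np.unique(labels)) < 2:
        raise InvalidArgumentError("both classes must be present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocReport(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


def confusion(labels: np.ndarray, scores: np.ndarray,
              threshold: float = 0.5) -> ConfusionReport:
    """Confusion counts at a probability threshold (positive = glioma)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.size == 0:
        raise InvalidArgumentError("empty input")
    if not set(np.unique(labels)) <= {0, 1}:
        raise InvalidArgumentError("labels must be binary 0/1")
    pred = scores >= threshold
    actual = labels.astype(bool)
    return ConfusionReport(
        tp=int(np.sum(pred & actual)),
        fn=int(np.sum(~pred & actual)),
        fp=int(np.sum(pred & ~actual)),
        tn=int(np.sum(~pred & ~actual)),
    )


def recon_report(y: np.ndarray, y_hat: np.ndarray,
                 ppm_axis: Optional[np.ndarray] = None) -> ReconReport:
    """Batch reconstruction report over (N, n_points, 2) spectra."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape or y.ndim != 3:
        raise InvalidArgumentError("expected matching (N, n, 2) batches")
    ex_mse = per_example_mse(y, y_hat)
    ex_rmse = np.sqrt(ex_mse)
    infinite = bool(np.any(ex_mse == 0))
    with np.errstate(divide="ignore"):
        ex_psnr = 10.0 * np.log10(1.0 / ex_mse)
    finite_psnr = ex_psnr[np.isfinite(ex_psnr)]
    ex_ssim = np.array([ssim_1d(y[i], y_hat[i]) for i in range(len(y))])
    snr = None
    if ppm_axis is not None:
        ex_snr = np.array([snr_creatine(y_hat[i], ppm_axis=ppm_axis)
                           for i in range(len(y))])
        finite = ex_snr[np.isfinite(ex_snr)]
        if len(finite):
            snr = (float(finite.mean()), float(finite.std()))
    mean_sd = lambda a: (float(np.mean(a)), float(np.std(a))) if len(a) else (float("nan"),) * 2
    return ReconReport(mse=mean_sd(ex_mse), rmse=mean_sd(ex_rmse),
                       psnr=mean_sd(finite_psnr), ssim=mean_sd(ex_ssim),
                       snr_creatine=snr, n=len(y), psnr_infinite=infinite)
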