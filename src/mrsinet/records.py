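"""Core array-record types passed between pipeline stages.

A *FID* (free induction decay) is the raw complex time-domain MR signal;
its Fourier transform is the spectrum a spectroscopist reads.  Records
carry the acquisition grid so downstream code can map array indices to
chemical shift (ppm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .errors import InvalidArgumentError

N_POINTS_DEFAULT = 1024


@dataclass
class AcquisitionGrid:
    """Time/frequency sampling of an acquisition.

    Attributes
    ----------
    dwell_time : float
        Seconds between FID samples, ``1 / spectral_width``.
    time_axis : ndarray
        Seconds for each of the ``n_points`` samples, starting at 0.
    ppm_axis : ndarray
        Chemical-shift axis (ascending) for the fftshifted spectrum.
    larmor_frequency : float
        Proton Larmor frequency in MHz; 1 ppm corresponds to this many Hz.
    """

    dwell_time: float
    time_axis: np.ndarray
    ppm_axis: np.ndarray
    larmor_frequency: float

    def __post_init__(self) -> None:
        if len(self.time_axis) != len(self.ppm_axis):
            raise InvalidArgumentError("time_axis and ppm_axis lengths differ")
        if not np.all(np.diff(self.ppm_axis) > 0):
            raise InvalidArgumentError("ppm_axis must be ascending")

    @property
    def n_points(self) -> int:
        return len(self.time_axis)

    @property
    def spectral_width(self) -> float:
        return 1.0 / self.dwell_time

    def ppm_window(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of ppm bins within [lo, hi]."""
        if lo > hi:
            raise InvalidArgumentError(f"empty ppm window [{lo}, {hi}]")
        return (self.ppm_axis >= lo) & (self.ppm_axis <= hi)


@dataclass
class FidRecord:
    """A complex time-domain signal plus its acquisition context."""

    samples: np.ndarray
    grid: AcquisitionGrid
    field_strength: float
    seed_provenance: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.complex128)
        if self.samples.ndim != 1:
            raise InvalidArgumentError("FID samples must be one-dimensional")
        if len(self.samples) != self.grid.n_points:
            raise InvalidArgumentError(
                f"FID length {len(self.samples)} != grid n_points {self.grid.n_points}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise InvalidArgumentError("FID contains non-finite samples")

    def copy_with(self, samples: np.ndarray) -> "FidRecord":
        return FidRecord(samples=samples, grid=self.grid,
                         field_strength=self.field_strength,
                         seed_provenance=self.seed_provenance)


@dataclass
class SpectrumRecord:
    """A frequency-domain spectrum, channels normalized to [0, 1].

    ``real_part``/``imag_part`` are stored fftshifted so they align with the
    ascending ``ppm_axis``.  A channel that was constant before min-max
    normalization is stored all-zero and flagged ``degenerate``.
    """

    real_part: np.ndarray
    imag_part: np.ndarray
    ppm_axis: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.real_part = np.asarray(self.real_part, dtype=np.float64)
        self.imag_part = np.asarray(self.imag_part, dtype=np.float64)
        if not (len(self.real_part) == len(self.imag_part) == len(self.ppm_axis)):
            raise InvalidArgumentError("spectrum channel / axis lengths differ")

    @property
    def channels(self) -> np.ndarray:
        """(n_points, 2) stacked real/imaginary channels."""
        return np.stack([self.real_part, self.imag_part], axis=-1)


@dataclass
class LabeledExample:
    """An augmented FID with a binary tissue label (1 = glioma)."""

    fid: FidRecord
    label: int
    profile_name: str = ""

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise InvalidArgumentError(f"label must be 0 or 1, got {self.label}")


@dataclass
class SplitArrays:
    """One split's arrays, laid out as in the on-disk container.

    Arrays are float32 with shape (N, n_points, 2) — real and imaginary
    channels last.  ``labels`` is None for unlabeled (reconstruction)
    datasets.
    """

    fids: np.ndarray
    targets: np.ndarray
    ppm_axis: np.ndarray
    labels: Optional[np.ndarray] = None
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fids)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test splits from one simulator run."""

    train: SplitArrays
    validation: SplitArrays
    test: SplitArrays
    split_fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    master_seed: int = 0

    def splits(self) -> Dict[str, SplitArrays]:
        return {"train": self.train, "validation": self.validation,
                "test": self.test}
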