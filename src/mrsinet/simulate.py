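"""Whole-spectrum simulation: composition, augmentation, dataset generation.

A simulated example is built in a fixed order:

1. draw per-metabolite concentrations uniformly within literature ranges
   for normal adult brain (or a tumor-shifted profile);
2. compose the clean FID as the concentration-weighted sum of basis FIDs;
3. the *target* is the Fourier spectrum of that clean FID, min-max
   normalized to [0, 1] per channel;
4. the *input* is the clean FID after augmentation:
   zero-order phase shift -> Lorentzian line broadening -> intensity
   scale -> residual water -> additive white Gaussian noise.

The target never depends on augmentation draws, so the learning task is
simultaneous domain transformation and denoising.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .basis import (BRAIN_METABOLITES, INTRINSIC_T2_DEFAULT, build_basis,
                    ppm_to_offset_hz)
from .errors import (ConfigurationError, DataError, InvalidArgumentError,
                     UnknownMetaboliteError)
from .records import (AcquisitionGrid, DatasetSplit, FidRecord,
                      SpectrumRecord, SplitArrays)

#: Normal adult brain concentration ranges, mmol/L (min, max).
NORMAL_BRAIN_CONCENTRATIONS_MM: Dict[str, Tuple[float, float]] = {
    "Ala": (0.1, 1.5),
    "Asp": (1.0, 2.0),
    "Cr": (5.5, 7.0),
    "GABA": (1.0, 2.0),
    "Glc": (1.0, 2.0),
    "Gln": (1.5, 5.0),
    "Glu": (6.0, 9.0),
    "Gly": (1.5, 2.5),
    "GPC": (0.5, 2.0),
    "GPE": (0.5, 2.0),
    "GSH": (1.5, 3.0),
    "Ins": (3.0, 5.0),
    "Lac": (0.2, 1.0),
    "NAA": (7.0, 10.0),
    "NAAG": (0.5, 3.0),
    "PCh": (0.5, 2.0),
    "PCr": (3.0, 5.5),
    "PEtn": (1.0, 2.0),
    "Ser": (0.5, 1.0),
    "ScyIns": (0.1, 0.3),
    "Tau": (2.0, 6.0),
}

#: Phantom tube composition, mmol/L (fixed concentrations).
PHANTOM_CONCENTRATIONS_MM: Dict[str, float] = {
    "NAA": 6.0, "Glu": 8.0, "GABA": 1.0, "Cr": 4.0,
    "Cho": 5.0, "Ins": 8.0, "Lac": 4.0,
}

#: Global intensity scale applied to every clean FID before noise.
#: Calibrated once against the simulation-time SNR definition — the
#: time-domain creatine signal amplitude over the white-noise magnitude
#: sigma — so that SNR spans an interval containing [1, 3] as sigma
#: sweeps its [0.05, 1] range (the mid-range creatine FID amplitude is
#: ~0.94, giving SNR ~0.94 at sigma = 1 and ~18.8 at sigma = 0.05).
INTENSITY_SCALE_DEFAULT = 0.03

#: Creatine reference values for the SNR calibration above.
CR_MEAN_CONCENTRATION_MM = 6.25   # midpoint of the 5.5-7.0 mmol/L range
CR_TOTAL_PROTONS = 5.0            # CH3 (3H) + CH2 (2H)

#: Linewidth of the residual water resonance (T2 in seconds, ~4 Hz FWHM).
WATER_T2_S = 0.08


@dataclass
class ConcentrationRanges:
    """Uniform sampling ranges (min, max) per metabolite, mmol/L."""

    ranges: Dict[str, Tuple[float, float]] = dc_field(
        default_factory=lambda: dict(NORMAL_BRAIN_CONCENTRATIONS_MM))

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise InvalidArgumentError(
                    f"{name}: concentration min {lo} > max {hi}")

    def scaled(self, factors: Mapping[str, float]) -> "ConcentrationRanges":
        """New ranges with (min, max) of selected metabolites multiplied."""
        new = dict(self.ranges)
        for name, f in factors.items():
            if name not in new:
                raise UnknownMetaboliteError(name)
            lo, hi = new[name]
            new[name] = (lo * f, hi * f)
        return ConcentrationRanges(ranges=new)

    @property
    def metabolites(self) -> List[str]:
        return list(self.ranges.keys())


@dataclass
class AugmentParams:
    """Augmentation draw ranges (uniform) and fixed scales.

    ``phase_range`` radians, ``broadening_range`` Hz, ``noise_range`` is
    the per-channel Gaussian standard deviation of the additive white
    noise.  ``water_amplitude`` scales a residual water line relative to
    the creatine peak height (0 disables).
    """

    phase_range: Tuple[float, float] = (-np.pi / 4, np.pi / 4)
    broadening_range: Tuple[float, float] = (0.0, 40.0)
    noise_range: Tuple[float, float] = (0.05, 1.0)
    water_amplitude: float = 0.0
    intensity_scale: float = INTENSITY_SCALE_DEFAULT

    def __post_init__(self) -> None:
        for name in ("phase_range", "broadening_range", "noise_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidArgumentError(f"{name}: min {lo} > max {hi}")
        if self.broadening_range[0] < 0 or self.noise_range[0] < 0:
            raise InvalidArgumentError("broadening and noise must be >= 0")
        if self.water_amplitude < 0:
            raise InvalidArgumentError("water_amplitude must be >= 0")


@dataclass
class ClassProfile:
    """A labeled concentration profile for synthetic cohort generation."""

    label: str
    concentration_ranges: ConcentrationRanges
    description: str = ""


def simulation_snr(sigma: float,
                   intensity_scale: float = INTENSITY_SCALE_DEFAULT) -> float:
    """Simulation-time SNR: scaled creatine FID amplitude over noise SD.

    This is the calibration-time definition (creatine signal / white
    noise magnitude); the spectroscopic in-vivo definition lives in
    :func:`mrsinet.metrics.snr_creatine`.
    """
    if sigma <= 0:
        raise InvalidArgumentError("sigma must be positive")
    return intensity_scale * CR_MEAN_CONCENTRATION_MM * CR_TOTAL_PROTONS / sigma


def healthy_profile() -> ClassProfile:
    """Normal adult brain concentrations (the literature table)."""
    return ClassProfile(label="healthy",
                        concentration_ranges=ConcentrationRanges(),
                        description="normal adult brain concentration ranges")


def glioma_profile() -> ClassProfile:
    """Glioma-like metabolic profile.

    Elevated total choline (GPC+PCh x3, membrane turnover), reduced NAA
    (x0.4, neuronal loss), elevated lactate (x4) and glutamate/glutamine
    (x1.5, crowding the 2.25 ppm region with Glx/2-HG-like signal).
    """
    ranges = ConcentrationRanges().scaled(
        {"GPC": 3.0, "PCh": 3.0, "NAA": 0.4, "Lac": 4.0,
         "Glu": 1.5, "Gln": 1.5})
    return ClassProfile(label="glioma", concentration_ranges=ranges,
                        description="elevated tCho/Lac/Glx, reduced NAA")


def default_profiles() -> List[ClassProfile]:
    return [healthy_profile(), glioma_profile()]


def phantom_preset() -> Tuple[List[str], ConcentrationRanges]:
    """The 7-metabolite structural-metabolic phantom composition.

    Concentrations are fixed (min = max), with free choline as the
    choline species.  Sampling from these degenerate ranges always
    returns the same composition.
    """
    ranges = ConcentrationRanges(
        ranges={m: (c, c) for m, c in PHANTOM_CONCENTRATIONS_MM.items()})
    return list(PHANTOM_CONCENTRATIONS_MM.keys()), ranges


# ---------------------------------------------------------------------------
# Single-record operations (thin wrappers over the array kernels below)
# ---------------------------------------------------------------------------

def sample_concentrations(ranges: ConcentrationRanges,
                          rng: np.random.Generator) -> Dict[str, float]:
    """Draw one concentration per metabolite, uniform within its range."""
    return {m: float(rng.uniform(lo, hi))
            for m, (lo, hi) in ranges.ranges.items()}


def compose_fid(concentrations: Mapping[str, float],
                basis_fids: Mapping[str, FidRecord],
                grid: AcquisitionGrid) -> FidRecord:
    """Concentration-weighted complex sum of basis FIDs."""
    unknown = set(concentrations) - set(basis_fids)
    if unknown:
        raise UnknownMetaboliteError(", ".join(sorted(unknown)))
    out = np.zeros(grid.n_points, dtype=np.complex128)
    field_strength = 3.0
    for m, c in concentrations.items():
        out += c * basis_fids[m].samples
        field_strength = basis_fids[m].field_strength
    return FidRecord(samples=out, grid=grid, field_strength=field_strength)


def apply_phase(fid: FidRecord, phi: float) -> FidRecord:
    """Zero-order phase shift: multiply every sample by exp(i*phi)."""
    if abs(phi) > np.pi:
        raise InvalidArgumentError(f"|phase| {abs(phi):.3f} > pi")
    if abs(phi) > np.pi / 4 + 1e-12:
        warnings.warn("phase shift outside the [-pi/4, pi/4] augmentation "
                      "range", stacklevel=2)
    return fid.copy_with(fid.samples * np.exp(1j * phi))


def apply_broadening(fid: FidRecord, lb: float,
                     grid: AcquisitionGrid) -> FidRecord:
    """Lorentzian line broadening: exponential apodization exp(-pi*lb*t).

    Convolves every spectral line with a Lorentzian of FWHM ``lb`` Hz,
    i.e. peak FWHMs grow additively by ``lb``.
    """
    if lb < 0:
        raise InvalidArgumentError(f"line broadening must be >= 0, got {lb}")
    return fid.copy_with(fid.samples * np.exp(-np.pi * lb * grid.time_axis))


def add_noise(fid: FidRecord, sigma: float,
              rng: np.random.Generator) -> FidRecord:
    """Additive white Gaussian noise, SD ``sigma`` per channel."""
    if sigma < 0:
        raise InvalidArgumentError(f"noise magnitude must be >= 0, got {sigma}")
    if sigma == 0:
        return fid.copy_with(fid.samples.copy())
    noise = rng.normal(0.0, sigma, size=(fid.grid.n_points, 2))
    return fid.copy_with(fid.samples + noise[:, 0] + 1j * noise[:, 1])


def _water_unit_fid(grid: AcquisitionGrid) -> np.ndarray:
    """Unit-amplitude residual-water FID (line at the 4.7 ppm carrier)."""
    return np.exp(-grid.time_axis / WATER_T2_S).astype(np.complex128)


def _magnitude_peak(spec_mag: np.ndarray, grid: AcquisitionGrid,
                    lo: float, hi: float) -> float:
    window = grid.ppm_window(lo, hi)
    return float(spec_mag[window].max())


def add_water(fid: FidRecord, amplitude: float,
              grid: AcquisitionGrid) -> FidRecord:
    """Add a residual water line at 4.7 ppm (the carrier, offset 0 Hz).

    The line is scaled so its magnitude-spectrum peak height equals
    ``amplitude`` times the creatine 3.03 ppm peak height of the input
    FID, emulating non-water-suppressed acquisition.
    """
    if amplitude < 0:
        raise InvalidArgumentError("water amplitude must be >= 0")
    if amplitude == 0:
        return fid.copy_with(fid.samples.copy())
    water = _water_unit_fid(grid)
    spec = np.abs(np.fft.fftshift(np.fft.fft(fid.samples)))
    cr_peak = _magnitude_peak(spec, grid, 2.9, 3.1)
    water_peak = float(np.abs(np.fft.fftshift(np.fft.fft(water))).max())
    scale = amplitude * cr_peak / water_peak
    return fid.copy_with(fid.samples + scale * water)


def target_spectrum(clean_fid: FidRecord) -> SpectrumRecord:
    """Ground-truth spectrum: DFT of the clean FID, [0, 1] per channel.

    The complex spectrum is fftshifted to ascending-frequency (ascending
    ppm) order, then the real and imaginary channels are min-max
    normalized independently.  A constant channel is returned all-zero
    with the ``degenerate`` flag set.
    """
    spec = np.fft.fftshift(np.fft.fft(clean_fid.samples))
    channels = np.stack([spec.real, spec.imag], axis=-1)
    normalized, degenerate = _minmax_channels(channels[None])
    return SpectrumRecord(real_part=normalized[0, :, 0],
                          imag_part=normalized[0, :, 1],
                          ppm_axis=clean_fid.grid.ppm_axis,
                          degenerate=bool(degenerate[0]))


# ---------------------------------------------------------------------------
# Vectorized dataset generation
# ---------------------------------------------------------------------------

def _minmax_channels(channels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Min-max normalize (N, n, 2) arrays per example and channel.

    Returns the normalized array and a boolean (N,) flag marking examples
    with at least one constant (degenerate) channel, whose channels map
    to zeros.
    """
    lo = channels.min(axis=1, keepdims=True)
    hi = channels.max(axis=1, keepdims=True)
    span = hi - lo
    degenerate_ch = span <= 0
    safe_span = np.where(degenerate_ch, 1.0, span)
    out = (channels - lo) / safe_span
    out = np.where(degenerate_ch, 0.0, out)
    return out, degenerate_ch.any(axis=(1, 2))


def _line_matrix(basis_set, grid: AcquisitionGrid) -> np.ndarray:
    """(n_metabolites, n_points) undecayed complex line sums.

    The per-sample phase advance of a line depends on its ppm offset and
    the dwell-time x Larmor product, which is field-invariant under the
    proportional spectral-width convention, so one matrix serves all
    field strengths; only the decay envelope varies with field.
    """
    t = grid.time_axis
    rows = []
    for m in basis_set.metabolites:
        row = np.zeros(grid.n_points, dtype=np.complex128)
        for line in basis_set.resonances[m]:
            offset = ppm_to_offset_hz(line.chemical_shift,
                                      basis_set.reference_ppm,
                                      grid.larmor_frequency)
            row += line.relative_amplitude * np.exp(2j * np.pi * offset * t)
        rows.append(row)
    return np.asarray(rows)


@dataclass
class _SimDraws:
    """All random draws of one generation run, made before any synthesis."""

    concentrations: np.ndarray      # (N, n_metabolites)
    fields: np.ndarray              # (N,) tesla
    phases: np.ndarray              # (N,) radians
    broadenings: np.ndarray         # (N,) Hz
    noise_sigmas: np.ndarray        # (N,)
    labels: Optional[np.ndarray]    # (N,) int8 or None
    metabolites: List[str]


def _draw_parameters(n: int, ranges_per_example: Sequence[ConcentrationRanges],
                     aug: AugmentParams, rng: np.random.Generator,
                     field_range: Tuple[float, float],
                     labels: Optional[np.ndarray],
                     discrete_fields: bool) -> _SimDraws:
    metabolites = ranges_per_example[0].metabolites
    lo = np.array([[rp.ranges[m][0] for m in metabolites]
                   for rp in ranges_per_example])
    hi = np.array([[rp.ranges[m][1] for m in metabolites]
                   for rp in ranges_per_example])
    conc = rng.uniform(size=(n, len(metabolites))) * (hi - lo) + lo
    if discrete_fields:
        fields = rng.choice(np.array(field_range), size=n)
    else:
        fields = rng.uniform(field_range[0], field_range[1], size=n)
    phases = rng.uniform(*aug.phase_range, size=n)
    broadenings = rng.uniform(*aug.broadening_range, size=n)
    sigmas = rng.uniform(*aug.noise_range, size=n)
    return _SimDraws(conc, fields, phases, broadenings, sigmas, labels,
                     metabolites)


def _synthesize(draws: _SimDraws, aug: AugmentParams,
                grid: AcquisitionGrid, line_matrix: np.ndarray,
                intrinsic_t2: float, noise_rng: np.random.Generator,
                chunk: int = 2048) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized synthesis; returns (fids, targets, degenerate_flags).

    Chunked to bound peak memory; chunking does not change results
    because all parameter draws precede synthesis and noise is drawn
    sequentially in example order.
    """
    n = len(draws.concentrations)
    n_pts = grid.n_points
    fids = np.empty((n, n_pts, 2), dtype=np.float32)
    targets = np.empty((n, n_pts, 2), dtype=np.float32)
    degenerate = np.zeros(n, dtype=bool)
    sample_idx = np.arange(n_pts)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        conc = draws.concentrations[sl]
        # dwell time scales as 1/field under the proportional-SW convention
        dwell = grid.dwell_time * 3.0 / draws.fields[sl]
        t = dwell[:, None] * sample_idx[None, :]
        clean = (conc @ line_matrix) * np.exp(-t / intrinsic_t2)
        spec = np.fft.fftshift(np.fft.fft(clean, axis=1), axes=1)
        ch = np.stack([spec.real, spec.imag], axis=-1)
        tgt, deg = _minmax_channels(ch)
        targets[sl] = tgt.astype(np.float32)
        degenerate[sl] = deg
        aug_fid = clean * np.exp(1j * draws.phases[sl])[:, None]
        aug_fid *= np.exp(-np.pi * draws.broadenings[sl][:, None] * t)
        aug_fid *= aug.intensity_scale
        if aug.water_amplitude > 0:
            mag = np.abs(spec)
            window = grid.ppm_window(2.9, 3.1)
            cr_peak = mag[:, window].max(axis=1) * aug.intensity_scale
            water = np.exp(-t / WATER_T2_S)
            water_peak = np.abs(
                np.fft.fftshift(np.fft.fft(water, axis=1), axes=1)).max(axis=1)
            aug_fid += (aug.water_amplitude * cr_peak / water_peak)[:, None] * water
        noise = noise_rng.normal(size=(sl.stop - sl.start, n_pts, 2))
        noise *= draws.noise_sigmas[sl][:, None, None]
        fids[sl, :, 0] = (aug_fid.real + noise[:, :, 0]).astype(np.float32)
        fids[sl, :, 1] = (aug_fid.imag + noise[:, :, 1]).astype(np.float32)
    return fids, targets, degenerate


def split_sizes(n: int, fractions: Tuple[float, float, float]) -> Tuple[int, int, int]:
    """Floor-based split sizes; the remainder goes to train."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"split fractions {fractions} do not sum to 1")
    if any(f < 0 for f in fractions):
        raise ConfigurationError("split fractions must be non-negative")
    n_val = int(np.floor(n * fractions[1]))
    n_test = int(np.floor(n * fractions[2]))
    n_train = n - n_val - n_test
    return n_train, n_val, n_test


def _package_splits(fids, targets, labels, grid, fractions, master_seed,
                    provenance) -> DatasetSplit:
    n = len(fids)
    n_train, n_val, n_test = split_sizes(n, fractions)
    bounds = [(0, n_train), (n_train, n_train + n_val), (n_train + n_val, n)]
    splits = []
    # inputs share one global scale so relative intensities stay comparable
    scale = float(np.abs(fids[:n_train, 0, :]).max()) if n_train else 1.0
    scale = scale if scale > 0 else 1.0
    prov = dict(provenance, input_scale=scale)
    for lo, hi in bounds:
        splits.append(SplitArrays(
            fids=fids[lo:hi] / np.float32(scale),
            targets=targets[lo:hi],
            ppm_axis=grid.ppm_axis.copy(),
            labels=None if labels is None else labels[lo:hi],
            provenance=prov,
        ))
    return DatasetSplit(train=splits[0], validation=splits[1], test=splits[2],
                        split_fractions=tuple(fractions), master_seed=master_seed)


def _rngs(master_seed: int) -> Tuple[np.random.Generator, np.random.Generator]:
    seq = np.random.SeedSequence(master_seed)
    params_seq, noise_seq = seq.spawn(2)
    return (np.random.default_rng(params_seq), np.random.default_rng(noise_seq))


def generate_dataset(n: int,
                     ranges: Optional[ConcentrationRanges] = None,
                     aug: Optional[AugmentParams] = None,
                     split_fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
                     master_seed: int = 0,
                     field_range: Tuple[float, float] = (3.0, 7.0),
                     discrete_fields: bool = False,
                     metabolites: Optional[Sequence[str]] = None,
                     intrinsic_t2: float = INTRINSIC_T2_DEFAULT,
                     ) -> DatasetSplit:
    """Generate n paired (augmented FID, clean target spectrum) examples.

    Fully reproducible from ``master_seed``; splits are disjoint with
    floor-based sizes and the remainder assigned to train.
    """
    if n < 10:
        raise InvalidArgumentError(f"n must be >= 10, got {n}")
    ranges = ranges or ConcentrationRanges()
    aug = aug or AugmentParams()
    base_metabs = metabolites if metabolites is not None else \
        [m for m in BRAIN_METABOLITES if m in ranges.ranges]
    basis_set, grid, _ = build_basis(3.0, metabolites=base_metabs,
                                     intrinsic_t2=intrinsic_t2)
    line_matrix = _line_matrix(basis_set, grid)
    params_rng, noise_rng = _rngs(master_seed)
    sub_ranges = ConcentrationRanges(
        ranges={m: ranges.ranges[m] for m in basis_set.metabolites})
    draws = _draw_parameters(n, [sub_ranges] * n, aug, params_rng,
                             field_range, None, discrete_fields)
    fids, targets, _ = _synthesize(draws, aug, grid, line_matrix,
                                   intrinsic_t2, noise_rng)
    provenance = {"master_seed": master_seed, "n": n, "kind": "paired",
                  "field_range": list(field_range),
                  "intensity_scale": aug.intensity_scale}
    return _package_splits(fids, targets, None, grid, split_fractions,
                           master_seed, provenance)


def generate_labeled_dataset(n_per_class: int,
                             profiles: Optional[Sequence[ClassProfile]] = None,
                             aug: Optional[AugmentParams] = None,
                             split_fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1),
                             master_seed: int = 0,
                             field_range: Tuple[float, float] = (3.0, 7.0),
                             discrete_fields: bool = False,
                             intrinsic_t2: float = INTRINSIC_T2_DEFAULT,
                             ) -> DatasetSplit:
    """Balanced two-class dataset: n_per_class examples per profile label.

    Examples are interleave-shuffled deterministically before splitting,
    so every split keeps an approximately balanced class mix.
    """
    profiles = list(profiles) if profiles is not None else default_profiles()
    labels_set = {p.label for p in profiles}
    if len(profiles) < 2 or len(labels_set) < 2:
        raise DataError(f"need >= 2 profiles with distinct labels, got "
                        f"{[p.label for p in profiles]}")
    aug = aug or AugmentParams()
    basis_set, grid, _ = build_basis(3.0, intrinsic_t2=intrinsic_t2)
    line_matrix = _line_matrix(basis_set, grid)
    params_rng, noise_rng = _rngs(master_seed)
    n_total = n_per_class * len(profiles)
    ranges_seq: List[ConcentrationRanges] = []
    label_arr = np.empty(n_total, dtype=np.int8)
    # interleave classes (profile order shuffled per round) so that every
    # contiguous split stays balanced to within one example per class
    for round_idx in range(n_per_class):
        order = params_rng.permutation(len(profiles))
        for k, pi in enumerate(order):
            p = profiles[pi]
            pos = round_idx * len(profiles) + k
            ranges_seq.append(ConcentrationRanges(
                ranges={m: p.concentration_ranges.ranges[m]
                        for m in basis_set.metabolites}))
            label_arr[pos] = 1 if p.label == "glioma" else 0
    draws = _draw_parameters(n_total, ranges_seq, aug, params_rng,
                             field_range, label_arr, discrete_fields)
    fids, targets, _ = _synthesize(draws, aug, grid, line_matrix,
                                   intrinsic_t2, noise_rng)
    provenance = {"master_seed": master_seed, "n": n_total, "kind": "labeled",
                  "n_per_class": n_per_class,
                  "profiles": [p.label for p in profiles],
                  "field_range": list(field_range),
                  "intensity_scale": aug.intensity_scale}
    return _package_splits(fids, targets, label_arr, grid, split_fractions,
                           master_seed, provenance)
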