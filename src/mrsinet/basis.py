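"""Metabolite spectral basis: noiseless per-metabolite FID synthesis.

Each metabolite is approximated as a small set of Lorentzian lines at
literature chemical shifts with proton-count-weighted amplitudes, read
from the bundled ``data/resonances.csv`` table.  A basis FID is the sum
of complex exponentials, one per resonance line, under a mild intrinsic
Lorentzian decay; whole-brain spectra are then concentration-weighted
sums of these basis FIDs.

J-coupling evolution is not modelled (multiplets are collapsed to their
centre positions), so echo time is carried as metadata only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import ConfigurationError, InvalidArgumentError, UnknownMetaboliteError
from .records import AcquisitionGrid, FidRecord, N_POINTS_DEFAULT

#: Gyromagnetic ratio of the proton, MHz per tesla.
PROTON_GYROMAGNETIC_RATIO_MHZ_PER_T = 42.576

#: Carrier (reference) position: water, ppm.
REFERENCE_PPM = 4.7

#: Spectral width at 3 T; scaled proportionally with field so the ppm
#: span (~15.7 ppm) is field-invariant.
SPECTRAL_WIDTH_3T_HZ = 2000.0

#: Default intrinsic T2 (s): ~2 Hz natural linewidth before augmentation.
INTRINSIC_T2_DEFAULT = 0.15

#: Default echo time metadata (ms).
ECHO_TIME_DEFAULT_MS = 35.0

#: The 21 brain metabolites of the simulation basis (concentration table
#: order).  Free choline ("Cho") is reserved for the phantom preset.
BRAIN_METABOLITES: Tuple[str, ...] = (
    "Ala", "Asp", "Cr", "GABA", "Glc", "Gln", "Glu", "Gly", "GPC", "GPE",
    "GSH", "Ins", "Lac", "NAA", "NAAG", "PCh", "PCr", "PEtn", "Ser",
    "ScyIns", "Tau",
)


@dataclass(frozen=True)
class MetaboliteResonance:
    """One Lorentzian line: position (ppm) and proton-weighted amplitude."""

    metabolite_name: str
    chemical_shift: float
    relative_amplitude: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.chemical_shift <= 10.0:
            raise InvalidArgumentError(
                f"chemical shift {self.chemical_shift} ppm outside [0, 10]"
            )
        if self.relative_amplitude <= 0:
            raise InvalidArgumentError("relative amplitude must be positive")


@dataclass
class BasisSet:
    """Per-metabolite resonance lines plus acquisition parameters."""

    resonances: Dict[str, List[MetaboliteResonance]]
    field_strength: float
    echo_time: float = ECHO_TIME_DEFAULT_MS
    spectral_width: float = SPECTRAL_WIDTH_3T_HZ
    n_points: int = N_POINTS_DEFAULT
    reference_ppm: float = REFERENCE_PPM

    def __post_init__(self) -> None:
        if not 3.0 <= self.field_strength <= 7.0:
            raise InvalidArgumentError(
                f"field strength {self.field_strength} T outside [3, 7]"
            )

    @property
    def metabolites(self) -> List[str]:
        return list(self.resonances.keys())


def load_resonance_table(path: Optional[str] = None) -> Dict[str, List[MetaboliteResonance]]:
    """Read the resonance CSV (metabolite, ppm, relative_amplitude)."""
    if path is None:
        source = resources.files("mrsinet.data").joinpath("resonances.csv")
        text = source.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: Dict[str, List[MetaboliteResonance]] = {}
    rows = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    for row in csv.DictReader(rows):
        res = MetaboliteResonance(
            metabolite_name=row["metabolite"].strip(),
            chemical_shift=float(row["ppm"]),
            relative_amplitude=float(row["relative_amplitude"]),
        )
        table.setdefault(res.metabolite_name, []).append(res)
    return table


def larmor_frequency(field_strength: float) -> float:
    """Proton Larmor frequency in MHz for a field in tesla (γ·B0)."""
    if field_strength <= 0:
        raise InvalidArgumentError(f"field strength must be positive, got {field_strength}")
    return PROTON_GYROMAGNETIC_RATIO_MHZ_PER_T * field_strength


def ppm_to_offset_hz(shift: float, reference_ppm: float, larmor: float) -> float:
    """Frequency offset (Hz) of a chemical shift relative to the carrier.

    With ``larmor`` in MHz, 1 ppm equals ``larmor`` Hz, so the offset is
    ``(shift - reference_ppm) * larmor``; a line at the carrier is 0 Hz.
    """
    if larmor <= 0:
        raise InvalidArgumentError(f"larmor frequency must be positive, got {larmor}")
    return (shift - reference_ppm) * larmor


def make_grid(field_strength: float,
              spectral_width: Optional[float] = None,
              n_points: int = N_POINTS_DEFAULT,
              reference_ppm: float = REFERENCE_PPM) -> AcquisitionGrid:
    """Build the time/ppm sampling grid for a field strength."""
    if n_points < 2:
        raise InvalidArgumentError("n_points must be >= 2")
    if spectral_width is None:
        spectral_width = SPECTRAL_WIDTH_3T_HZ * field_strength / 3.0
    larmor = larmor_frequency(field_strength)
    dwell = 1.0 / spectral_width
    time_axis = np.arange(n_points) * dwell
    freq_axis = np.fft.fftshift(np.fft.fftfreq(n_points, d=dwell))
    ppm_axis = reference_ppm + freq_axis / larmor
    return AcquisitionGrid(dwell_time=dwell, time_axis=time_axis,
                           ppm_axis=ppm_axis, larmor_frequency=larmor)


def metabolite_fid(metabolite: str, basis: BasisSet, grid: AcquisitionGrid,
                   intrinsic_t2: float = INTRINSIC_T2_DEFAULT) -> FidRecord:
    """Noiseless FID of one metabolite: a sum of decaying complex exponentials.

    ``FID[t] = sum_lines a_l * exp(2πi * offset_l * t) * exp(-t / T2)``;
    at t = 0 the real part therefore equals the summed line amplitudes.
    """
    if metabolite not in basis.resonances:
        raise UnknownMetaboliteError(metabolite)
    if intrinsic_t2 <= 0:
        raise InvalidArgumentError("intrinsic_t2 must be positive")
    t = grid.time_axis
    fid = np.zeros(len(t), dtype=np.complex128)
    for line in basis.resonances[metabolite]:
        offset = ppm_to_offset_hz(line.chemical_shift, basis.reference_ppm,
                                  grid.larmor_frequency)
        fid += line.relative_amplitude * np.exp(2j * np.pi * offset * t)
    fid *= np.exp(-t / intrinsic_t2)
    return FidRecord(samples=fid, grid=grid, field_strength=basis.field_strength)


def build_basis(field_strength: float = 3.0,
                spectral_width: Optional[float] = None,
                n_points: int = N_POINTS_DEFAULT,
                metabolites: Optional[Sequence[str]] = None,
                exclude: Sequence[str] = (),
                intrinsic_t2: float = INTRINSIC_T2_DEFAULT,
                ) -> Tuple[BasisSet, AcquisitionGrid, Dict[str, FidRecord]]:
    """Synthesize the noiseless basis FID of every metabolite.

    Deterministic: two calls with identical arguments return bit-identical
    arrays.  Raises :class:`ConfigurationError` if the spectral width does
    not cover the 0.5-4.5 ppm metabolite span at the given field.
    """
    grid = make_grid(field_strength, spectral_width, n_points)
    half_span_ppm = grid.spectral_width / 2.0 / grid.larmor_frequency
    if REFERENCE_PPM - half_span_ppm > 0.5 or REFERENCE_PPM + half_span_ppm < 4.5:
        raise ConfigurationError(
            f"spectral width {grid.spectral_width:.0f} Hz does not cover "
            f"0.5-4.5 ppm at {field_strength} T"
        )
    table = load_resonance_table()
    wanted = list(metabolites) if metabolites is not None else list(BRAIN_METABOLITES)
    wanted = [m for m in wanted if m not in set(exclude)]
    missing = [m for m in wanted if m not in table]
    if missing:
        raise UnknownMetaboliteError(", ".join(missing))
    basis = BasisSet(
        resonances={m: table[m] for m in wanted},
        field_strength=field_strength,
        spectral_width=grid.spectral_width,
        n_points=n_points,
    )
    fids = {m: metabolite_fid(m, basis, grid, intrinsic_t2) for m in wanted}
    return basis, grid, fids
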