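"""Spectral power distribution containers.

A :class:`Spectrum` is the universal input object of the package: a
uniformly sampled spectral quantity (irradiance in W/m²/nm or radiance in
W/m²/sr/nm) on a wavelength grid.  The grid is stored as integers in
units of 0.1 nm (``start_dnm``, ``step_dnm``) so that grid equality and
uniformity checks are exact — IEEE 754 float spacing such as
``np.arange(380, 780.1, 0.1)`` would otherwise produce spurious
non-uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

__all__ = ["Mode", "Spectrum", "SpectrumBatch", "STANDARD_SPAN_NM"]

#: Calculation span used throughout: 380–780 nm.
STANDARD_SPAN_NM = (380.0, 780.0)


class Mode(str, Enum):
    """Physical interpretation of the spectral values."""

    IRRADIANCE = "irradiance"  # W/m²/nm
    RADIANCE = "radiance"      # W/m²/sr/nm


def _to_dnm(value_nm: float) -> int:
    """Convert nm to exact integer decinanometres (0.1 nm units)."""
    dnm = round(float(value_nm) * 10)
    if abs(dnm - value_nm * 10) > 1e-6:
        raise ValueError(
            f"wavelength {value_nm} nm is not representable on a 0.1 nm "
            f"integer grid"
        )
    return int(dnm)


@dataclass(frozen=True)
class Spectrum:
    """A uniformly sampled spectral power distribution.

    Parameters
    ----------
    start_dnm:
        Wavelength of the first sample in 0.1 nm units (integer).
    step_dnm:
        Grid spacing in 0.1 nm units (positive integer).
    values:
        Spectral density values, one per grid point.  Interpreted per nm
        (W/m²/nm or W/m²/sr/nm depending on ``mode``).
    mode:
        Irradiance or radiance.
    label:
        Free-text identifier (CSV column header, illuminant name, ...).
    """

    start_dnm: int
    step_dnm: int
    values: np.ndarray
    mode: Mode = Mode.IRRADIANCE
    label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.step_dnm <= 0:
            raise ValueError("step must be positive")
        if values.ndim != 1 or values.size < 2:
            raise ValueError("a spectrum needs at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("spectral values must be finite")

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_nm(
        cls,
        start_nm: float,
        step_nm: float,
        values: np.ndarray,
        mode: Mode = Mode.IRRADIANCE,
        label: str = "",
    ) -> "Spectrum":
        return cls(_to_dnm(start_nm), _to_dnm(step_nm), np.asarray(values, float),
                   Mode(mode), label)

    # -- grid accessors -------------------------------------------------

    @property
    def start_nm(self) -> float:
        return self.start_dnm / 10.0

    @property
    def step_nm(self) -> float:
        return self.step_dnm / 10.0

    @property
    def end_nm(self) -> float:
        return (self.start_dnm + self.step_dnm * (len(self.values) - 1)) / 10.0

    @property
    def wavelengths(self) -> np.ndarray:
        """Wavelength grid in nm."""
        idx = np.arange(len(self.values))
        return (self.start_dnm + idx * self.step_dnm) / 10.0

    def same_grid(self, other: "Spectrum") -> bool:
        return (
            self.start_dnm == other.start_dnm
            and self.step_dnm == other.step_dnm
            and len(self.values) == len(other.values)
        )

    # -- arithmetic helpers ---------------------------------------------

    def scaled(self, k: float) -> "Spectrum":
        return replace(self, values=self.values * k)

    def with_label(self, label: str) -> "Spectrum":
        return replace(self, label=label)

    def value_at(self, wavelength_nm: float) -> float:
        """Linear interpolation inside the native span, 0 outside."""
        return float(
            np.interp(wavelength_nm, self.wavelengths, self.values,
                      left=0.0, right=0.0)
        )

    def __eq__(self, other: object) -> bool:  # dataclass eq breaks on ndarray
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            self.start_dnm == other.start_dnm
            and self.step_dnm == other.step_dnm
            and self.mode == other.mode
            and self.label == other.label
            and np.array_equal(self.values, other.values)
        )


@dataclass
class SpectrumBatch:
    """One or more spectra sharing a single wavelength grid and mode."""

    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spectra:
            raise ValueError("batch must contain at least one spectrum")
        first = self.spectra[0]
        for s in self.spectra[1:]:
            if not first.same_grid(s):
                raise ValueError("all spectra in a batch must share one grid")
            if s.mode != first.mode:
                raise ValueError("all spectra in a batch must share one mode")

    @property
    def mode(self) -> Mode:
        return self.spectra[0].mode

    @property
    def wavelengths(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]
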