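"""Tristimulus integration, photometry and chromaticity systems.

Tristimulus values are computed by rectangular summation on the
spectrum's own grid, X = Σ S(λ)·x̄(λ)·Δλ, with the colour-matching
functions linearly resampled to that grid.  This matches the
spreadsheet-style convention of the standard calculation tools; the
difference from trapezoidal integration is below 0.1 % at 5 nm spacing.

The photometric constant is exactly 683 lm/W.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .reference_data import get_table
from .spectrum import Mode, Spectrum

__all__ = [
    "LUMINOUS_EFFICACY",
    "TristimulusSet",
    "ChromaticitySystem",
    "ChromaticityPoint",
    "tristimulus",
    "luminous_quantity",
    "chromaticity",
    "spectrum_uv",
]

LUMINOUS_EFFICACY = 683.0  # lm/W, exact


@dataclass(frozen=True)
class TristimulusSet:
    """Observer-weighted integrals X, Y, Z of a spectrum."""

    X: float
    Y: float
    Z: float
    observer: str

    def as_array(self) -> np.ndarray:
        return np.array([self.X, self.Y, self.Z])


class ChromaticitySystem(str, Enum):
    XY_1931 = "xy_1931"
    XY10_1964 = "xy10_1964"
    UV_1960 = "uv_1960"
    UPVP_1976 = "upvp_1976"


@dataclass(frozen=True)
class ChromaticityPoint:
    system: ChromaticitySystem
    a: float
    b: float

    def __iter__(self):
        return iter((self.a, self.b))


class UndefinedChromaticityError(ValueError):
    """Raised when a chromaticity denominator is zero."""


def tristimulus(spectrum: Spectrum,
                observer: str = "cie1931_2deg") -> TristimulusSet:
    """X, Y, Z by rectangular summation on the spectrum's grid."""
    obs = get_table(observer)
    wl = spectrum.wavelengths
    xb = np.interp(wl, obs.wavelengths, obs.xbar, left=0.0, right=0.0)
    yb = np.interp(wl, obs.wavelengths, obs.ybar, left=0.0, right=0.0)
    zb = np.interp(wl, obs.wavelengths, obs.zbar, left=0.0, right=0.0)
    dl = spectrum.step_nm
    s = spectrum.values
    return TristimulusSet(
        float(np.sum(s * xb) * dl),
        float(np.sum(s * yb) * dl),
        float(np.sum(s * zb) * dl),
        observer,
    )


def luminous_quantity(spectrum: Spectrum) -> float:
    """Illuminance [lx] (irradiance mode) or luminance [cd/m²] (radiance).

    683 lm/W times the V(λ)-weighted sum; V(λ) is the ybar column of the
    1931 observer, so this equals 683·Y by construction.
    """
    return LUMINOUS_EFFICACY * tristimulus(spectrum, "cie1931_2deg").Y


def chromaticity(tris: TristimulusSet,
                 system: ChromaticitySystem | str) -> ChromaticityPoint:
    """Project tristimulus values into one of the four chromaticity systems."""
    system = ChromaticitySystem(system)
    X, Y, Z = tris.X, tris.Y, tris.Z
    if system in (ChromaticitySystem.XY_1931, ChromaticitySystem.XY10_1964):
        den = X + Y + Z
        if den <= 0:
            raise UndefinedChromaticityError("X+Y+Z is zero")
        return ChromaticityPoint(system, X / den, Y / den)
    den = X + 15.0 * Y + 3.0 * Z
    if den <= 0:
        raise UndefinedChromaticityError("X+15Y+3Z is zero")
    if system is ChromaticitySystem.UV_1960:
        return ChromaticityPoint(system, 4.0 * X / den, 6.0 * Y / den)
    return ChromaticityPoint(system, 4.0 * X / den, 9.0 * Y / den)


def spectrum_uv(spectrum: Spectrum) -> ChromaticityPoint:
    """Convenience: CIE 1960 (u, v) of a spectrum with the 2° observer."""
    return chromaticity(tristimulus(spectrum), ChromaticitySystem.UV_1960)
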