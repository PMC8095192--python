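"""CIE S 026-style α-opic quantities.

For each photoreceptor channel α ∈ {sc, mc, lc, rh, mel} (S-, M-,
L-cone-opic, rhodopic, melanopic):

* α-opic (ir)radiance  E_α = 1000 · Σ S(λ)·s_α(λ)·Δλ  [mW/m² or
  mW/m²/sr], with s_α the unit-peak sensitivity;
* α-opic ELR (efficacy of luminous radiation)  ELR_α = E_α / photopic
  (il)luminance  [mW/lm];
* α-opic EDI/EDL (equivalent daylight (il)luminance)
  EDI_α = E_α / ELR_α^D65  [lx or cd/m²], where ELR_α^D65 is the ELR of
  the reference D65 daylight.

The D65 normalisation constants are computed once from the package's
own D65 and sensitivity tables and frozen in ``_d65_constants.py`` (15
significant digits) so report outputs are bit-for-bit reproducible; a
test asserts that recomputation from the tables reproduces them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorimetry import luminous_quantity
from .reference_data import ALPHA_CHANNELS, get_table
from .spectrum import Mode, Spectrum

__all__ = [
    "ALPHA_CHANNELS",
    "AlphaOpicSet",
    "alpha_opic_irradiance",
    "alpha_opic_edi",
    "alpha_opic_elr",
    "alpha_opic_set",
    "compute_d65_elr",
    "d65_elr_constants",
]


@dataclass(frozen=True)
class AlphaOpicSet:
    """Per-channel α-opic (ir)radiance, EDI/EDL and ELR of one spectrum."""

    e_alpha: dict[str, float]   # mW/m² (irradiance) or mW/m²/sr (radiance)
    edi: dict[str, float]       # lx or cd/m²
    elr: dict[str, float]       # mW/lm; NaN when illuminance is zero
    photopic: float             # lx or cd/m²
    mode: Mode


def compute_d65_elr() -> dict[str, float]:
    """Recompute the D65 ELR constants [mW/lm] from the vendored tables."""
    d65 = get_table("illuminants")["D65"]
    e = alpha_opic_irradiance(d65)
    lum = luminous_quantity(d65)
    return {ch: e[ch] / lum for ch in ALPHA_CHANNELS}


def d65_elr_constants() -> dict[str, float]:
    """The frozen D65 ELR constants [mW/lm]."""
    from ._d65_constants import D65_ELR
    return dict(D65_ELR)


def alpha_opic_irradiance(spectrum: Spectrum) -> dict[str, float]:
    """α-opic (ir)radiance per channel in mW/m² (mW/m²/sr in radiance mode)."""
    action = get_table("action_spectra")
    wl = spectrum.wavelengths
    dl = spectrum.step_nm
    out = {}
    for ch in ALPHA_CHANNELS:
        s_alpha = np.interp(wl, action.wavelengths, action[ch],
                            left=0.0, right=0.0)
        out[ch] = 1000.0 * float(np.sum(spectrum.values * s_alpha) * dl)
    return out


def alpha_opic_elr(spectrum: Spectrum) -> dict[str, float]:
    """α-opic ELR per channel [mW/lm]; NaN channels when illuminance is 0."""
    e = alpha_opic_irradiance(spectrum)
    lum = luminous_quantity(spectrum)
    if lum <= 0.0:
        return {ch: float("nan") for ch in ALPHA_CHANNELS}
    return {ch: e[ch] / lum for ch in ALPHA_CHANNELS}


def alpha_opic_edi(spectrum: Spectrum) -> dict[str, float]:
    """α-opic equivalent daylight (il)luminance per channel [lx or cd/m²]."""
    e = alpha_opic_irradiance(spectrum)
    ref = d65_elr_constants()
    return {ch: e[ch] / ref[ch] for ch in ALPHA_CHANNELS}


def alpha_opic_set(spectrum: Spectrum) -> AlphaOpicSet:
    """All α-opic quantities of one spectrum in a single pass."""
    e = alpha_opic_irradiance(spectrum)
    lum = luminous_quantity(spectrum)
    ref = d65_elr_constants()
    edi = {ch: e[ch] / ref[ch] for ch in ALPHA_CHANNELS}
    if lum > 0.0:
        elr = {ch: e[ch] / lum for ch in ALPHA_CHANNELS}
    else:
        elr = {ch: float("nan") for ch in ALPHA_CHANNELS}
    return AlphaOpicSet(e, edi, elr, lum, spectrum.mode)
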