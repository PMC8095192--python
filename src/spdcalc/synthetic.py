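"""Deterministic generators of test spectra.

Every generator is a pure function of (family, parameters, seed) on the
standard 380–780 nm, 1 nm grid.  The seed only matters when the optional
noise amplitude is non-zero (default 0), so the default outputs are
exactly reproducible without it.

Families: planckian, gaussian_led, rgb_led, monochromatic, notch,
equal_energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .reference_data import planckian_spd, standard_grid
from .spectrum import Mode, Spectrum

__all__ = ["SyntheticSpec", "generate"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class SyntheticSpec:
    family: str
    params: dict = dc_field(default_factory=dict)
    seed: int = 0
    noise_sigma: float = 0.0
    mode: Mode = Mode.IRRADIANCE


def _gauss(grid: np.ndarray, peak_nm: float, fwhm_nm: float) -> np.ndarray:
    sigma = fwhm_nm * _FWHM_TO_SIGMA
    return np.exp(-0.5 * ((grid - peak_nm) / sigma) ** 2)


def generate(spec: SyntheticSpec) -> Spectrum:
    """Materialise a synthetic spectrum from its specification."""
    grid = standard_grid(1.0)
    p = spec.params
    family = spec.family

    if family == "planckian":
        base = planckian_spd(p["T"], grid)
        vals = base.values * p.get("scale", 1.0)
        mode = spec.mode if "mode" not in p else Mode(p["mode"])
    elif family == "gaussian_led":
        vals = np.zeros_like(grid)
        for peak, fwhm, weight in p.get(
                "bands", [(p.get("peak", 560.0), p.get("fwhm", 80.0), 1.0)]):
            vals += weight * _gauss(grid, peak, fwhm)
        vals *= p.get("scale", 1.0)
        mode = spec.mode
    elif family == "rgb_led":
        w_r, w_g, w_b = p.get("weights", (1.0, 1.0, 1.0))
        fwhm = p.get("fwhm", 25.0)
        vals = (w_b * _gauss(grid, 450.0, fwhm)
                + w_g * _gauss(grid, 530.0, fwhm)
                + w_r * _gauss(grid, 620.0, fwhm)) * p.get("scale", 1.0)
        mode = spec.mode
    elif family == "monochromatic":
        vals = np.zeros_like(grid)
        idx = int(round(p["peak"] - grid[0]))
        if not 0 <= idx < len(grid):
            raise ValueError(f"monochromatic peak {p['peak']} nm outside "
                             "the 380-780 nm grid")
        vals[idx] = p.get("power", 1.0)
        mode = spec.mode
    elif family == "notch":
        base = generate(SyntheticSpec(p.get("base_family", "planckian"),
                                      p.get("base_params", {"T": p.get("T", 3000.0)}),
                                      spec.seed, 0.0, spec.mode))
        depth = p["depth"]
        if not 0.0 <= depth <= 1.0:
            raise ValueError("notch depth must lie in [0, 1]")
        notch = depth * _gauss(grid, p.get("centre", 575.0),
                               p.get("fwhm", 40.0))
        vals = base.values * (1.0 - notch)
        mode = base.mode
    elif family == "equal_energy":
        vals = np.full_like(grid, p.get("level", 1.0))
        mode = spec.mode
    else:
        raise ValueError(f"unknown synthetic family {family!r}")

    if spec.noise_sigma > 0.0:
        rng = np.random.default_rng(spec.seed)
        vals = np.clip(vals + rng.normal(0.0, spec.noise_sigma, vals.shape),
                       0.0, None)
    return Spectrum.from_nm(grid[0], 1.0, vals, mode,
                            label=f"{family}")
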