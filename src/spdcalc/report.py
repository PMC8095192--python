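"""Assembly of the full per-spectrum quantity report.

One column per spectrum, one row per quantity.  Quantities that are
undefined under the |Duv| > 0.05 rule (or a zero denominator) carry the
literal string "N/A".  Each spectrum is computed independently, so
results do not depend on batch composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alpha_opic import ALPHA_CHANNELS, alpha_opic_set
from .cct import cct_ohno, cct_robertson
from .colorimetry import (ChromaticitySystem, chromaticity, luminous_quantity,
                          tristimulus)
from .fidelity import Tm30Block, fidelity_report
from .spectrum import Mode, Spectrum, SpectrumBatch

__all__ = ["RunConfig", "SpectrumResult", "compute_report", "report_rows",
           "intermediate_rows"]

_CHANNEL_LABELS = {
    "sc": "S-cone-opic", "mc": "M-cone-opic", "lc": "L-cone-opic",
    "rh": "rhodopic", "mel": "melanopic",
}

#: spectra allowed per run unless power mode removes the cap
DEFAULT_SPECTRUM_CAP = 5


@dataclass
class RunConfig:
    mode: Mode = Mode.IRRADIANCE
    tm30: bool = False
    notation: str = "linear"        # "linear" | "exponential"
    intermediates: bool = False
    power: bool = False
    planck_step_percent: float = 0.25
    max_spectra: int = DEFAULT_SPECTRUM_CAP

    def effective_cap(self) -> int | None:
        return None if self.power else self.max_spectra


@dataclass
class SpectrumResult:
    """Every quantity computed for a single spectrum."""

    label: str
    photopic: float
    chrom: dict[str, float]
    cct_robertson: object
    cct_ohno: object
    alpha: object
    fidelity: object
    tm30: Tm30Block | None = None
    x10y10_defined: bool = True
    intermediates: dict[str, float] = field(default_factory=dict)


def compute_spectrum(spectrum: Spectrum, config: RunConfig) -> SpectrumResult:
    tris2 = tristimulus(spectrum, "cie1931_2deg")
    tris10 = tristimulus(spectrum, "cie1964_10deg")
    xy = chromaticity(tris2, ChromaticitySystem.XY_1931)
    uv = chromaticity(tris2, ChromaticitySystem.UV_1960)
    upvp = chromaticity(tris2, ChromaticitySystem.UPVP_1976)
    xy10 = chromaticity(tris10, ChromaticitySystem.XY10_1964)

    ohno = cct_ohno((uv.a, uv.b))
    robertson = cct_robertson((uv.a, uv.b), duv=ohno.duv)
    fid = fidelity_report(spectrum, include_tm30=config.tm30)
    alpha = alpha_opic_set(spectrum)

    inter = {
        "X (2deg)": tris2.X, "Y (2deg)": tris2.Y, "Z (2deg)": tris2.Z,
        "X10": tris10.X, "Y10": tris10.Y, "Z10": tris10.Z,
        "u": uv.a, "v": uv.b,
        "CCT Ohno raw [K]": ohno.cct_K, "Duv (Ohno)": ohno.duv,
        "CCT Robertson raw [K]": robertson.cct_K,
    }
    if fid.rf_i is not None:
        for i, v in enumerate(fid.rf_i, start=1):
            inter[f"Rf sample {i}"] = float(v)
    if config.tm30 and fid.tm30 is not None:
        for j in range(16):
            inter[f"CVG bin {j + 1} test a'"] = fid.tm30.cvg_test[j, 0]
            inter[f"CVG bin {j + 1} test b'"] = fid.tm30.cvg_test[j, 1]
            inter[f"CVG bin {j + 1} ref a'"] = fid.tm30.cvg_reference[j, 0]
            inter[f"CVG bin {j + 1} ref b'"] = fid.tm30.cvg_reference[j, 1]

    return SpectrumResult(
        label=spectrum.label,
        photopic=luminous_quantity(spectrum),
        chrom={"x": xy.a, "y": xy.b, "x10": xy10.a, "y10": xy10.b,
               "u": uv.a, "v": uv.b, "u'": upvp.a, "v'": upvp.b},
        cct_robertson=robertson,
        cct_ohno=ohno,
        alpha=alpha,
        fidelity=fid,
        tm30=fid.tm30,
        intermediates=inter,
    )


def compute_report(batch: SpectrumBatch,
                   config: RunConfig | None = None) -> list[SpectrumResult]:
    config = config or RunConfig()
    cap = config.effective_cap()
    if cap is not None and len(batch) > cap:
        raise ValueError(
            f"batch has {len(batch)} spectra, over the cap of {cap}; "
            "enable power mode to remove the limit")
    return [compute_spectrum(s, config) for s in batch]


def _na(value, cond: bool):
    return value if cond else "N/A"


def report_rows(results: list[SpectrumResult],
                mode: Mode, tm30: bool = False) -> list[tuple[str, list]]:
    """Report as (label, per-spectrum values) rows."""
    radiance = mode is Mode.RADIANCE
    lum_label = "Luminance [cd/m2]" if radiance else "Illuminance [lx]"
    e_unit = "mW/m2/sr" if radiance else "mW/m2"
    edi_label = "EDL [cd/m2]" if radiance else "EDI [lx]"

    rows: list[tuple[str, list]] = []

    def add(label: str, getter):
        rows.append((label, [getter(r) for r in results]))

    add("Spectrum", lambda r: r.label)
    add(lum_label, lambda r: r.photopic)
    for key, label in [("x", "CIE 1931 x"), ("y", "CIE 1931 y"),
                       ("x10", "CIE 1964 x10"), ("y10", "CIE 1964 y10"),
                       ("u", "CIE 1960 u"), ("v", "CIE 1960 v"),
                       ("u'", "CIE 1976 u'"), ("v'", "CIE 1976 v'")]:
        add(label, lambda r, k=key: r.chrom[k])
    add("CCT (Robertson) [K]",
        lambda r: _na(r.cct_robertson.cct_K, r.cct_robertson.valid))
    add("CCT (Ohno) [K]", lambda r: _na(r.cct_ohno.cct_K, r.cct_ohno.valid))
    add("Duv", lambda r: r.cct_ohno.duv)
    add("Ra", lambda r: _na(r.fidelity.ra, r.fidelity.ra is not None))
    for i in range(8):
        add(f"R{i + 1}",
            lambda r, i=i: _na(None if r.fidelity.r_i is None
                               else int(r.fidelity.r_i[i]),
                               r.fidelity.r_i is not None))
    add("Rf (CIE 224)", lambda r: _na(r.fidelity.rf,
                                      r.fidelity.rf is not None))
    for ch in ALPHA_CHANNELS:
        add(f"{_CHANNEL_LABELS[ch]} (ir)radiance [{e_unit}]",
            lambda r, c=ch: r.alpha.e_alpha[c])
    for ch in ALPHA_CHANNELS:
        add(f"{_CHANNEL_LABELS[ch]} {edi_label}",
            lambda r, c=ch: r.alpha.edi[c])
    for ch in ALPHA_CHANNELS:
        add(f"{_CHANNEL_LABELS[ch]} ELR [mW/lm]",
            lambda r, c=ch: _na(r.alpha.elr[c],
                                np.isfinite(r.alpha.elr[c])))
    add("Melanopic ratio (mel EDI / photopic)",
        lambda r: _na(r.alpha.edi["mel"] / r.photopic, r.photopic > 0))
    if tm30:
        add("Rf (TM-30)", lambda r: _na(None if r.tm30 is None else r.tm30.rf,
                                        r.tm30 is not None))
        add("Rg", lambda r: _na(None if r.tm30 is None else r.tm30.rg,
                                r.tm30 is not None))
        add("Rcs,h1 [%]",
            lambda r: _na(None if r.tm30 is None else r.tm30.rcs_h1,
                          r.tm30 is not None))
        add("Rf,h1", lambda r: _na(None if r.tm30 is None else r.tm30.rf_h1,
                                   r.tm30 is not None))
    return rows


def intermediate_rows(results: list[SpectrumResult]) -> list[tuple[str, list]]:
    labels: list[str] = []
    for r in results:
        for k in r.intermediates:
            if k not in labels:
                labels.append(k)
    rows = [("Spectrum", [r.label for r in results])]
    for label in labels:
        rows.append((label,
                     [r.intermediates.get(label, "N/A") for r in results]))
    return rows
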