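"""Colour rendering (Ra), colour fidelity (Rf) and gamut (TM-30) indices.

Three index families share one structure — render a set of reflectance
samples under the test source and under a reference illuminant of the
same CCT, and score the colour differences:

* Ra: the legacy general colour rendering index.  8 test-colour
  samples, CIE 1964 U*V*W* space with a von Kries chromatic-adaptation
  correction; Robertson CCT selects the reference (Planckian below
  5000 K, daylight at/above).  Each R_i = 100 − 4.6·ΔE_i is rounded to
  the nearest whole number before averaging.
* Rf: the colour fidelity index.  99 colour-evaluation samples rendered
  with the 1964 10° observer, differences in CAM02-UCS, cf = 6.73,
  Rf = 10·ln(exp(Rf′/10)+1) with Rf′ = 100 − cf·mean(ΔE).  Ohno CCT
  selects the reference, blending Planckian → daylight linearly between
  4000 and 5000 K (equal weights at 4500 K).
* TM-30: same machinery with blend knees 4500–5500 K, plus the gamut
  index Rg (hue-bin polygon area ratio), the bin-1 chroma shift Rcs,h1
  and local fidelity Rf,h1, and the colour-vector-graphic polygons.

All indices are undefined (reported N/A) when |Duv| > 0.05.  Every
subindex is rounded to 15 significant digits before reuse, a
cross-implementation reproducibility measure with no effect on accuracy
beyond ~1e-6.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cct import DUV_VALIDITY_LIMIT, cct_ohno, cct_robertson
from .ciecam02 import CIE224_CONDITIONS, cam02ucs
from .colorimetry import ChromaticitySystem, chromaticity, tristimulus
from .reference_data import daylight_spd, get_table, planckian_spd, standard_grid
from .spectrum import Mode, Spectrum

__all__ = [
    "CF_RF",
    "ReferenceIlluminant",
    "FidelityReport",
    "Tm30Block",
    "reference_illuminant",
    "colour_rendering_ra",
    "colour_fidelity_rf",
    "tm30_quantities",
    "cvg_export",
]

CF_RF = 6.73  # CIE colour-fidelity scaling constant
_N_BINS = 16
_BIN_WIDTH_DEG = 360.0 / _N_BINS


def _round15(x):
    """Round to 15 significant digits (cross-tool reproducibility)."""
    return np.asarray([float(f"{v:.15g}") for v in np.atleast_1d(x)])


def _rf_scale(delta_e_mean: float) -> float:
    rf_prime = 100.0 - CF_RF * delta_e_mean
    return 10.0 * np.log(np.exp(rf_prime / 10.0) + 1.0)


@dataclass(frozen=True)
class ReferenceIlluminant:
    spectrum: Spectrum
    descriptor: str            # "planckian" | "daylight" | "blended"
    weight_planckian: float    # 1 pure Planckian … 0 pure daylight
    cct: float


@dataclass(frozen=True)
class Tm30Block:
    rf: float
    rg: float
    rcs_h1: float              # signed percent
    rf_h1: float
    cvg_test: np.ndarray       # (16, 2) normalised test bin means
    cvg_reference: np.ndarray  # (16, 2) normalised reference bin means
    valid: bool


@dataclass(frozen=True)
class FidelityReport:
    ra: float | None
    r_i: np.ndarray | None     # 8 integer subindices
    rf: float | None
    rf_i: np.ndarray | None    # 99 per-sample values
    reference: ReferenceIlluminant | None
    tm30: Tm30Block | None
    valid: bool


def reference_illuminant(cct: float, scheme: str = "cie224",
                         grid: np.ndarray | None = None) -> ReferenceIlluminant:
    """Reference SPD for a given CCT under one of the three schemes.

    cie224: Planckian below 4000 K, daylight above 5000 K, linear blend
    between (equal weights at 4500 K).  tm30: knees at 4500/5500 K.
    cie13_3: hard switch from Planckian to daylight at 5000 K.
    Blended components are normalised to equal tristimulus Y before
    mixing.
    """
    if grid is None:
        grid = standard_grid(1.0)
    knees = {"cie224": (4000.0, 5000.0), "tm30": (4500.0, 5500.0)}
    if scheme == "cie13_3":
        if cct < 5000.0:
            return ReferenceIlluminant(planckian_spd(cct, grid),
                                       "planckian", 1.0, cct)
        return ReferenceIlluminant(daylight_spd(min(cct, 25000.0), grid),
                                   "daylight", 0.0, cct)
    lo, hi = knees[scheme]
    if cct <= lo:
        return ReferenceIlluminant(planckian_spd(cct, grid),
                                   "planckian", 1.0, cct)
    if cct >= hi:
        return ReferenceIlluminant(daylight_spd(min(cct, 25000.0), grid),
                                   "daylight", 0.0, cct)
    w = (hi - cct) / (hi - lo)
    p = planckian_spd(cct, grid)
    d = daylight_spd(cct, grid)
    yp = tristimulus(p).Y
    yd = tristimulus(d).Y
    vals = w * p.values / yp + (1.0 - w) * d.values / yd
    blended = Spectrum.from_nm(grid[0], grid[1] - grid[0], vals,
                               Mode.IRRADIANCE, label=f"ref {cct:.0f} K")
    return ReferenceIlluminant(blended, "blended", w, cct)


# ---------------------------------------------------------------------------
# Ra (CIE 13.3 style)
# ---------------------------------------------------------------------------

def _sample_xyz(source: Spectrum, reflectances: np.ndarray,
                sample_wl: np.ndarray, observer: str) -> np.ndarray:
    """XYZ of each reflectance sample under ``source``, white Y = 100."""
    obs = get_table(observer)
    wl = source.wavelengths
    cmf = np.vstack([
        np.interp(wl, obs.wavelengths, band, left=0.0, right=0.0)
        for band in (obs.xbar, obs.ybar, obs.zbar)
    ])  # (3, n_wl)
    refl = np.vstack([
        np.interp(wl, sample_wl, r, left=0.0, right=0.0)
        for r in reflectances
    ])  # (n_samples, n_wl)
    s = source.values
    k = 100.0 / np.sum(s * cmf[1])
    return k * (refl * s) @ cmf.T  # (n_samples, 3)


def _uv1960(xyz: np.ndarray) -> np.ndarray:
    den = xyz[..., 0] + 15.0 * xyz[..., 1] + 3.0 * xyz[..., 2]
    return np.stack([4.0 * xyz[..., 0] / den, 6.0 * xyz[..., 1] / den],
                    axis=-1)


def _von_kries_cd(uv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    u, v = uv[..., 0], uv[..., 1]
    c = (4.0 - u - 10.0 * v) / v
    d = (1.708 * v + 0.404 - 1.481 * u) / v
    return c, d


def colour_rendering_ra(test: Spectrum) -> tuple[float | None, np.ndarray | None]:
    """General colour rendering index Ra and the 8 subindices R1–R8.

    Returns (None, None) when |Duv| > 0.05 (the N/A rule).
    """
    tris = tristimulus(test)
    uv_test = chromaticity(tris, ChromaticitySystem.UV_1960)
    robertson = cct_robertson((uv_test.a, uv_test.b))
    if not robertson.valid:
        return None, None

    ref = reference_illuminant(robertson.cct_K, "cie13_3",
                               grid=test.wavelengths)
    tcs = get_table("cie13_3_8tcs", step_nm=5.0)

    xyz_t = _sample_xyz(test, tcs.reflectances, tcs.wavelengths,
                        "cie1931_2deg")
    xyz_r = _sample_xyz(ref.spectrum, tcs.reflectances, tcs.wavelengths,
                        "cie1931_2deg")
    uv_t = _uv1960(xyz_t)
    uv_r = _uv1960(xyz_r)
    uvs_t = np.array([uv_test.a, uv_test.b])
    uvs_r = _uv1960(np.asarray(tristimulus(ref.spectrum).as_array()))

    # von Kries chromatic-adaptation correction of the test renderings
    c_st, d_st = _von_kries_cd(uvs_t[None, :])
    c_sr, d_sr = _von_kries_cd(uvs_r[None, :])
    c_k, d_k = _von_kries_cd(uv_t)
    denom = 16.518 + 1.481 * (c_sr / c_st) * c_k - (d_sr / d_st) * d_k
    u_corr = (10.872 + 0.404 * (c_sr / c_st) * c_k
              - 4.0 * (d_sr / d_st) * d_k) / denom
    v_corr = 5.520 / denom
    uv_t_corr = np.stack([u_corr, v_corr], axis=-1)

    def uvw_star(y: np.ndarray, uv: np.ndarray) -> np.ndarray:
        w = 25.0 * np.cbrt(y) - 17.0
        u_s = 13.0 * w * (uv[:, 0] - uvs_r[0])
        v_s = 13.0 * w * (uv[:, 1] - uvs_r[1])
        return np.stack([u_s, v_s, w], axis=-1)

    star_t = uvw_star(xyz_t[:, 1], uv_t_corr)
    star_r = uvw_star(xyz_r[:, 1], uv_r)
    delta_e = _round15(np.linalg.norm(star_t - star_r, axis=-1))
    r_i = np.round(100.0 - 4.6 * delta_e).astype(int)
    ra = float(np.mean(r_i))
    return ra, r_i


# ---------------------------------------------------------------------------
# Rf (CIE 224 style) and TM-30
# ---------------------------------------------------------------------------

def _resample_1nm(spectrum: Spectrum) -> Spectrum:
    from .spectra_io import resample  # local import avoids a cycle
    return resample(spectrum, 1.0)


def _ucs_pair(test: Spectrum, ref: Spectrum):
    """CAM02-UCS renderings of the 99 samples under test and reference."""
    ces = get_table("tm30_99ces", step_nm=5.0)
    out = []
    for src in (test, ref):
        xyz = _sample_xyz(src, ces.reflectances, ces.wavelengths,
                          "cie1964_10deg")
        white = np.asarray(tristimulus(src, "cie1964_10deg").as_array())
        white = white * (100.0 / white[1])
        out.append(cam02ucs(xyz, white, CIE224_CONDITIONS))
    return out


def colour_fidelity_rf(test: Spectrum, scheme: str = "cie224"):
    """Colour fidelity index Rf and the 99 per-sample subindices.

    The source is resampled to 1 nm over 380–780 nm by linear
    interpolation before calculation.  Returns (None, None, None) when
    |Duv| > 0.05; the third element is the ReferenceIlluminant used.
    """
    test1 = _resample_1nm(test)
    ohno = cct_ohno(test1)
    if not ohno.valid:
        return None, None, None
    ref = reference_illuminant(ohno.cct_K, scheme, grid=test1.wavelengths)

    ucs_t, ucs_r = _ucs_pair(test1, ref.spectrum)
    de = np.sqrt((ucs_t.jp - ucs_r.jp) ** 2 + (ucs_t.ap - ucs_r.ap) ** 2
                 + (ucs_t.bp - ucs_r.bp) ** 2)
    de = _round15(de)
    rf_i = _round15([_rf_scale(d) for d in de])
    rf = float(_rf_scale(float(np.mean(de))))
    return rf, rf_i, ref


def tm30_quantities(test: Spectrum) -> Tm30Block | None:
    """TM-30 Rf, Rg, Rcs,h1, Rf,h1 and the CVG polygons.

    Returns None when |Duv| > 0.05 (all quantities N/A).
    """
    test1 = _resample_1nm(test)
    ohno = cct_ohno(test1)
    if not ohno.valid:
        return None
    ref = reference_illuminant(ohno.cct_K, "tm30", grid=test1.wavelengths)
    ucs_t, ucs_r = _ucs_pair(test1, ref.spectrum)

    de = _round15(np.sqrt(
        (ucs_t.jp - ucs_r.jp) ** 2 + (ucs_t.ap - ucs_r.ap) ** 2
        + (ucs_t.bp - ucs_r.bp) ** 2))
    rf = float(_rf_scale(float(np.mean(de))))

    # hue-bin assignment by *reference* hue angle
    h_ref = np.degrees(np.arctan2(ucs_r.bp, ucs_r.ap)) % 360.0
    bins = np.minimum((h_ref / _BIN_WIDTH_DEG).astype(int), _N_BINS - 1)

    mean_t = np.zeros((_N_BINS, 2))
    mean_r = np.zeros((_N_BINS, 2))
    rcs_h1 = rf_h1 = None
    for j in range(_N_BINS):
        sel = bins == j
        if not np.any(sel):
            raise ValueError(
                f"hue bin {j + 1} contains no colour-evaluation samples")
        mean_t[j] = [ucs_t.ap[sel].mean(), ucs_t.bp[sel].mean()]
        mean_r[j] = [ucs_r.ap[sel].mean(), ucs_r.bp[sel].mean()]
        if j == 0:
            theta = np.radians((j + 0.5) * _BIN_WIDTH_DEG)
            shift = ((ucs_t.ap[sel] - ucs_r.ap[sel]) * np.cos(theta)
                     + (ucs_t.bp[sel] - ucs_r.bp[sel]) * np.sin(theta))
            chroma_ref = np.hypot(ucs_r.ap[sel], ucs_r.bp[sel]).mean()
            rcs_h1 = float(100.0 * shift.mean() / chroma_ref)
            rf_h1 = float(_rf_scale(float(de[sel].mean())))

    def polygon_area(pts: np.ndarray) -> float:
        x, y = pts[:, 0], pts[:, 1]
        return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    rg = float(100.0 * polygon_area(mean_t) / polygon_area(mean_r))

    # CVG normalisation: reference bin means mapped onto the unit circle
    chroma_r = np.hypot(mean_r[:, 0], mean_r[:, 1])
    cvg_ref = mean_r / chroma_r[:, None]
    cvg_test = mean_t / chroma_r[:, None]
    return Tm30Block(rf, rg, rcs_h1, rf_h1, cvg_test, cvg_ref, True)


def fidelity_report(test: Spectrum, include_tm30: bool = False) -> FidelityReport:
    """Ra, Rf and (optionally) the TM-30 block for one spectrum."""
    ra, r_i = colour_rendering_ra(test)
    rf, rf_i, ref = colour_fidelity_rf(test, "cie224")
    tm30 = tm30_quantities(test) if include_tm30 else None
    valid = rf is not None
    return FidelityReport(ra, r_i, rf, rf_i, ref, tm30, valid)


def cvg_export(block: Tm30Block | None, path, title: str = "") -> bool:
    """Write a colour-vector-graphic image; returns False for N/A blocks."""
    import warnings

    if block is None or not block.valid:
        warnings.warn("TM-30 block is N/A; no CVG written", stacklevel=2)
        return False

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    theta = np.linspace(0.0, 2.0 * np.pi, 361)
    ax.plot(np.cos(theta), np.sin(theta), color="0.4", lw=1.5,
            label="reference")
    closed = np.vstack([block.cvg_test, block.cvg_test[:1]])
    ax.plot(closed[:, 0], closed[:, 1], color="crimson", lw=2, label="test")
    ax.set_aspect("equal")
    ax.set_xlim(-1.6, 1.6)
    ax.set_ylim(-1.6, 1.6)
    ax.axis("off")
    corners = [
        (-1.55, 1.45, f"Rf {block.rf:.1f}"),
        (1.0, 1.45, f"Rg {block.rg:.1f}"),
        (-1.55, -1.5, f"Rcs,h1 {block.rcs_h1:.1f}%"),
        (1.0, -1.5, f"Rf,h1 {block.rf_h1:.1f}"),
    ]
    for x, y, text in corners:
        ax.text(x, y, text, fontsize=10)
    if title:
        ax.set_title(title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return True
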