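"""Standard observers, action spectra, illuminants and colour samples.

Tables with a published abridged tabulation (CIE 1931 2° and 1964 10°
colour-matching functions, scotopic V′(λ), the daylight characteristic
vectors S0/S1/S2, Illuminant C) are vendored as plain-text CSV files
under ``spdcalc/data`` and linearly interpolated to the requested grid.
Quantities with an exact analytic definition (Planckian radiators,
Illuminant A, the CIE daylight phases D50/D65/D75) are generated from
their defining formulas.

The remaining reference objects — the F/FL3/HP/LED illuminant series,
the 8 colour-rendering test samples, the 99 colour-evaluation samples
and the five photoreceptor (α-opic) sensitivities — are *synthetic
stand-ins*: physically plausible constructions with the right structure
(line + phosphor models, hue-diverse smooth reflectances, photopigment
nomograms at the corneal peak wavelengths).  They are deterministic and
documented, but they are not the official tabulations; calculations that
depend on them are meaningful relative to this package's own tables, not
as reproductions of standards-body numbers.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from .spectrum import Mode, Spectrum, STANDARD_SPAN_NM
from .tables import load_packaged_table

__all__ = [
    "ObserverTable",
    "ActionSpectrumSet",
    "IlluminantLibrary",
    "ColourSampleSet",
    "planckian_spd",
    "daylight_spd",
    "illuminant_a_spd",
    "get_table",
    "standard_grid",
    "C2",
]

#: Second radiation constant, CIE 015 convention [m·K].  Using the older
#: value 1.4380e-2 shifts CCT results by O(1 K).
C2 = 1.4388e-2

ALPHA_CHANNELS = ("sc", "mc", "lc", "rh", "mel")


def standard_grid(step_nm: float = 1.0) -> np.ndarray:
    """The default 380–780 nm calculation grid."""
    lo, hi = STANDARD_SPAN_NM
    n = int(round((hi - lo) / step_nm)) + 1
    return lo + step_nm * np.arange(n)


def _interp(grid: np.ndarray, wl: np.ndarray, val: np.ndarray) -> np.ndarray:
    """Linear interpolation; zero outside the table's native span."""
    return np.interp(grid, wl, val, left=0.0, right=0.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ObserverTable:
    """Colour-matching functions of a standard colorimetric observer."""

    name: str  # "cie1931_2deg" | "cie1964_10deg"
    wavelengths: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def resampled(self, grid: np.ndarray) -> "ObserverTable":
        return ObserverTable(
            self.name,
            np.asarray(grid, float),
            _interp(grid, self.wavelengths, self.xbar),
            _interp(grid, self.wavelengths, self.ybar),
            _interp(grid, self.wavelengths, self.zbar),
        )


@dataclass(frozen=True)
class ActionSpectrumSet:
    """Unit-peak photoreceptor sensitivities s_alpha(lambda).

    Channels: sc, mc, lc (S/M/L-cone-opic), rh (rhodopic), mel
    (melanopic).  The rhodopic channel is the vendored scotopic V′(λ)
    table normalised to unit peak on the grid; the cone and melanopsin
    channels are synthetic nomogram constructions (see module docstring).
    """

    wavelengths: np.ndarray
    sensitivities: dict[str, np.ndarray]

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.sensitivities[channel]

    def resampled(self, grid: np.ndarray) -> "ActionSpectrumSet":
        sens = {
            k: _interp(grid, self.wavelengths, v)
            for k, v in self.sensitivities.items()
        }
        sens = {k: v / v.max() for k, v in sens.items()}
        return ActionSpectrumSet(np.asarray(grid, float), sens)


@dataclass
class IlluminantLibrary:
    """Named relative SPDs for comparison and reference purposes."""

    spectra: dict[str, Spectrum] = field(default_factory=dict)

    def names(self) -> list[str]:
        return sorted(self.spectra)

    def __contains__(self, name: str) -> bool:
        return self._resolve(name) is not None

    def _resolve(self, name: str) -> str | None:
        lowered = {k.lower(): k for k in self.spectra}
        return lowered.get(name.strip().lower())

    def __getitem__(self, name: str) -> Spectrum:
        key = self._resolve(name)
        if key is None:
            raise KeyError(
                f"unknown illuminant {name!r}; valid names: "
                + ", ".join(self.names())
            )
        return self.spectra[key]


@dataclass(frozen=True)
class ColourSampleSet:
    """Spectral reflectances of a set of test-colour samples."""

    name: str  # "cie13_3_8tcs" | "tm30_99ces"
    wavelengths: np.ndarray
    reflectances: np.ndarray  # shape (n_samples, n_wavelengths)

    def __len__(self) -> int:
        return self.reflectances.shape[0]

    def resampled(self, grid: np.ndarray) -> "ColourSampleSet":
        refl = np.vstack([
            _interp(grid, self.wavelengths, r) for r in self.reflectances
        ])
        return ColourSampleSet(self.name, np.asarray(grid, float), refl)


# ---------------------------------------------------------------------------
# analytic generators
# ---------------------------------------------------------------------------

def planckian_spd(T: float, grid: np.ndarray | None = None) -> Spectrum:
    """Relative spectral radiance of a Planckian (blackbody) radiator.

    Planck's law with the CIE second radiation constant c2 = 1.4388e-2
    m·K, normalised to unit maximum over the grid (chromaticity and all
    ratio quantities are scale-free).
    """
    if not T > 0:
        raise ValueError(f"Planckian temperature must be positive, got {T}")
    if grid is None:
        grid = standard_grid()
    grid = np.asarray(grid, float)
    lam = grid * 1e-9  # m
    vals = lam ** -5.0 / np.expm1(C2 / (lam * T))
    vals = vals / vals.max()
    step = grid[1] - grid[0]
    return Spectrum.from_nm(grid[0], step, vals, Mode.RADIANCE,
                            label=f"Planckian {T:g} K")


def _daylight_locus_x(T: float) -> float:
    """CIE 015 daylight-locus chromaticity xD as a function of CCT."""
    if T <= 7000.0:
        return (-4.6070e9 / T**3 + 2.9678e6 / T**2 + 0.09911e3 / T
                + 0.244063)
    return -2.0064e9 / T**3 + 1.9018e6 / T**2 + 0.24748e3 / T + 0.237040


def daylight_spd(Tcct: float, grid: np.ndarray | None = None) -> Spectrum:
    """CIE daylight phase D(Tcct) reconstituted from S0, S1, S2.

    Valid for 4000 K ≤ Tcct ≤ 25000 K; below 4000 K the daylight locus
    is undefined and callers must use a Planckian reference instead.
    The mixing coefficients M1, M2 are rounded to three decimals per the
    CIE recipe; the result is normalised to 100 at 560 nm.
    """
    if not (4000.0 <= Tcct <= 25000.0):
        raise ValueError(
            f"daylight phases are defined for 4000-25000 K, got {Tcct}")
    if grid is None:
        grid = standard_grid()
    grid = np.asarray(grid, float)

    xd = _daylight_locus_x(Tcct)
    yd = -3.000 * xd**2 + 2.870 * xd - 0.275
    m = 0.0241 + 0.2562 * xd - 0.7341 * yd
    m1 = round((-1.3515 - 1.7703 * xd + 5.9114 * yd) / m, 3)
    m2 = round((0.0300 - 31.4424 * xd + 30.0717 * yd) / m, 3)

    names, data = load_packaged_table("daylight_components_10nm.csv")
    wl = data[:, 0]
    s0, s1, s2 = data[:, 1], data[:, 2], data[:, 3]
    vals = (_interp(grid, wl, s0) + m1 * _interp(grid, wl, s1)
            + m2 * _interp(grid, wl, s2))
    ref = float(np.interp(560.0, grid, vals))
    if ref > 0:
        vals = vals * (100.0 / ref)
    step = grid[1] - grid[0]
    return Spectrum.from_nm(grid[0], step, vals, Mode.IRRADIANCE,
                            label=f"D({Tcct:g} K)")


def illuminant_a_spd(grid: np.ndarray | None = None) -> Spectrum:
    """CIE Standard Illuminant A from its exact analytic definition."""
    if grid is None:
        grid = standard_grid()
    grid = np.asarray(grid, float)
    lam = grid * 1e-9
    ref = 560e-9
    # Blackbody at 2848 K under the historical c2 = 1.4350e-2; with the
    # current c2 = 1.4388e-2 the equivalent temperature is 2855.54 K.
    t_a = 2848.0 * (1.4388 / 1.4350)
    vals = (100.0 * (ref / lam) ** 5
            * np.expm1(C2 / (ref * t_a)) / np.expm1(C2 / (lam * t_a)))
    step = grid[1] - grid[0]
    return Spectrum.from_nm(grid[0], step, vals, Mode.IRRADIANCE, label="A")


# ---------------------------------------------------------------------------
# synthetic stand-in generators
# ---------------------------------------------------------------------------

def _gauss(grid: np.ndarray, centre: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - centre) / sigma) ** 2)


def _govardovskii(grid: np.ndarray, lambda_max: float) -> np.ndarray:
    """A1 visual-pigment template (alpha + beta band), unit peak.

    Used to construct synthetic stand-ins for photoreceptor
    sensitivities when placed at the corneal peak wavelength.
    """
    x = lambda_max / grid
    a = 0.8795 + 0.0459 * np.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (
        np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
        + np.exp(-14.9 * (1.104 - x)) + 0.674
    )
    lam_beta = 189.0 + 0.315 * lambda_max
    b_beta = -40.5 + 0.195 * lambda_max
    beta = 0.26 * np.exp(-(((grid - lam_beta) / b_beta) ** 2))
    s = alpha + beta
    return s / s.max()


# Corneal peak wavelengths used for the synthetic alpha-opic stand-ins.
_ALPHA_PEAKS_NM = {"sc": 448.0, "mc": 542.0, "lc": 568.0, "mel": 490.0}


@functools.lru_cache(maxsize=None)
def _action_spectra_1nm() -> ActionSpectrumSet:
    grid = standard_grid(1.0)
    sens: dict[str, np.ndarray] = {}
    for ch, peak in _ALPHA_PEAKS_NM.items():
        sens[ch] = _govardovskii(grid, peak)
    names, data = load_packaged_table("vprime_scotopic_5nm.csv")
    vp = _interp(grid, data[:, 0], data[:, 1])
    sens["rh"] = vp / vp.max()
    sens = {ch: sens[ch] for ch in ALPHA_CHANNELS}
    return ActionSpectrumSet(grid, sens)


def _fluorescent_spd(grid: np.ndarray, cct: float,
                     triphosphor: bool) -> np.ndarray:
    """Synthetic fluorescent-lamp model: mercury lines + phosphor bands."""
    mercury = (
        1.0 * _gauss(grid, 404.7, 2.0) + 2.2 * _gauss(grid, 435.8, 2.0)
        + 1.8 * _gauss(grid, 546.1, 2.0) + 0.7 * _gauss(grid, 577.0, 2.0)
    )
    warm = float(np.clip((6500.0 - cct) / (6500.0 - 2700.0), 0.0, 1.0))
    if triphosphor:
        phosphor = (
            (1.6 - 1.0 * warm) * _gauss(grid, 450.0, 12.0)
            + 1.4 * _gauss(grid, 544.0, 12.0)
            + (0.8 + 1.4 * warm) * _gauss(grid, 611.0, 10.0)
        )
    else:
        phosphor = (
            (1.3 - 0.9 * warm) * _gauss(grid, 480.0, 40.0)
            + (0.9 + 1.6 * warm) * _gauss(grid, 585.0, 70.0)
        )
    return mercury + 2.0 * phosphor


def _hp_spd(grid: np.ndarray, idx: int) -> np.ndarray:
    """Synthetic high-pressure discharge model (sodium/metal-halide)."""
    if idx <= 2:  # sodium-like: broadened D-line doublet + recombination
        width = 8.0 + 6.0 * idx
        return (2.5 * _gauss(grid, 589.0, width)
                + 1.2 * _gauss(grid, 569.0, width * 0.8)
                + 0.3 * _gauss(grid, 616.0, 20.0)
                + 0.10 + 0.25 * _gauss(grid, 500.0, 120.0))
    # metal-halide-like: multiline + continuum
    lines = [(405.0, 0.8), (436.0, 1.0), (535.0, 1.2), (546.0, 1.3),
             (578.0, 1.4), (589.0, 1.0), (630.0, 0.9)]
    spd = 0.35 + 0.6 * _gauss(grid, 540.0, 130.0)
    for c, w in lines:
        spd = spd + w * _gauss(grid, c, 6.0 + idx)
    return spd


def _led_spd(grid: np.ndarray, pump_nm: float, pump_sigma: float,
             bands: list[tuple[float, float, float]]) -> np.ndarray:
    spd = _gauss(grid, pump_nm, pump_sigma)
    for centre, sigma, weight in bands:
        spd = spd + weight * _gauss(grid, centre, sigma)
    return spd


@functools.lru_cache(maxsize=None)
def _illuminant_library() -> IlluminantLibrary:
    grid = standard_grid(1.0)
    step = grid[1] - grid[0]

    def as_spec(vals: np.ndarray, label: str) -> Spectrum:
        ref = float(np.interp(560.0, grid, vals))
        if ref > 0:
            vals = vals * (100.0 / ref)
        return Spectrum.from_nm(grid[0], step, vals, Mode.IRRADIANCE, label)

    lib: dict[str, Spectrum] = {}
    lib["A"] = illuminant_a_spd(grid)
    names, data = load_packaged_table("illuminant_c_10nm.csv")
    lib["C"] = as_spec(_interp(grid, data[:, 0], data[:, 1]), "C")
    for nominal in (5000, 6500, 7500):
        t = nominal * (1.4388 / 1.4380)
        lib[f"D{nominal // 100}"] = daylight_spd(t, grid).with_label(
            f"D{nominal // 100}")

    # Synthetic stand-ins (see module docstring): F, FL3.x, HP, LED series.
    f_ccts = [6430, 4230, 3450, 2940, 6350, 4150, 6500, 5000, 4150, 5000,
              4000, 3000]
    for i, cct in enumerate(f_ccts, start=1):
        tri = i in (10, 11, 12)
        lib[f"F{i}"] = as_spec(_fluorescent_spd(grid, cct, tri), f"F{i}")
    fl3_ccts = [2932, 3450, 4080, 2904, 4086, 3956, 4049, 5000, 6598,
                5000, 5854, 6509, 3969, 5009, 6598]
    for i, cct in enumerate(fl3_ccts, start=1):
        lib[f"FL3.{i}"] = as_spec(
            _fluorescent_spd(grid, cct, triphosphor=i > 7), f"FL3.{i}")
    for i in range(1, 6):
        lib[f"HP{i}"] = as_spec(_hp_spd(grid, i - 1), f"HP{i}")
    led_b_phos = [(600.0, 65.0, 5.0), (590.0, 65.0, 4.2), (575.0, 62.0, 3.6),
                  (565.0, 60.0, 3.0), (555.0, 58.0, 2.4)]
    for i, (c, s, w) in enumerate(led_b_phos, start=1):
        lib[f"LED-B{i}"] = as_spec(
            _led_spd(grid, 452.0, 10.0, [(c, s, w)]), f"LED-B{i}")
    lib["LED-BH1"] = as_spec(
        _led_spd(grid, 452.0, 10.0, [(560.0, 45.0, 2.4), (640.0, 12.0, 2.2)]),
        "LED-BH1")
    lib["LED-RGB1"] = as_spec(
        _led_spd(grid, 465.0, 11.0, [(535.0, 15.0, 1.9), (622.0, 12.0, 2.2)]),
        "LED-RGB1")
    lib["LED-V1"] = as_spec(
        _led_spd(grid, 410.0, 8.0, [(455.0, 20.0, 0.9), (560.0, 60.0, 2.6),
                                    (620.0, 30.0, 1.8)]), "LED-V1")
    lib["LED-V2"] = as_spec(
        _led_spd(grid, 410.0, 8.0, [(470.0, 25.0, 1.3), (555.0, 55.0, 3.0),
                                    (610.0, 28.0, 1.6)]), "LED-V2")
    return IlluminantLibrary(lib)


@functools.lru_cache(maxsize=None)
def _tcs8_synthetic() -> ColourSampleSet:
    """Synthetic stand-in for the 8 colour-rendering test samples.

    Moderate-chroma smooth reflectances whose hues step around the hue
    circle in the order of the standard sample set (red, yellow,
    yellow-green, green, blue-green, blue, violet, purple).
    """
    grid = standard_grid(5.0)
    params = [
        # base, [(centre, sigma, amp), ...]
        (0.22, [(625.0, 45.0, 0.38)]),                      # greyish red
        (0.22, [(585.0, 55.0, 0.40)]),                      # greyish yellow
        (0.18, [(555.0, 45.0, 0.45)]),                      # yellow-green
        (0.18, [(530.0, 40.0, 0.40)]),                      # green
        (0.20, [(495.0, 40.0, 0.36)]),                      # blue-green
        (0.18, [(462.0, 38.0, 0.42)]),                      # blue
        (0.18, [(445.0, 35.0, 0.38), (690.0, 55.0, 0.25)]),  # violet
        (0.20, [(452.0, 35.0, 0.30), (640.0, 60.0, 0.36)]),  # purple
    ]
    refl = []
    for base, bands in params:
        r = np.full_like(grid, base)
        for c, s, a in bands:
            r = r + a * _gauss(grid, c, s)
        refl.append(np.clip(r, 0.0, 1.0))
    return ColourSampleSet("cie13_3_8tcs", grid, np.vstack(refl))


@functools.lru_cache(maxsize=None)
def _ces99_synthetic() -> ColourSampleSet:
    """Synthetic stand-in for the 99 colour-evaluation samples.

    A deterministic hue/chroma-diverse family: 75 single-band smooth
    reflectances sweeping the spectral hues, plus 24 two-band
    (blue + red) reflectances covering the purple/magenta hues; base
    reflectance, band width and amplitude cycle so that lightness and
    chroma vary across samples as they do in the real sample set.
    """
    grid = standard_grid(5.0)
    refl = []
    for i in range(75):
        t = i / 74.0
        centre = 430.0 + t * (670.0 - 430.0)
        sigma = 22.0 + 18.0 * ((i * 7) % 5) / 4.0
        amp = 0.30 + 0.40 * ((i * 3) % 4) / 3.0
        base = 0.08 + 0.22 * ((i * 5) % 3) / 2.0
        r = base + amp * _gauss(grid, centre, sigma)
        # long-wavelength shoulder for the red end, as real pigments have
        if centre > 600.0:
            r = r + amp * 0.8 / (1.0 + np.exp(-(grid - centre - 20.0) / 12.0))
        refl.append(np.clip(r, 0.0, 1.0))
    for i in range(24):
        t = i / 23.0
        w_red = 0.15 + 0.7 * t
        amp = 0.35 + 0.25 * ((i * 3) % 3) / 2.0
        base = 0.08 + 0.18 * ((i * 5) % 4) / 3.0
        r = (base + amp * (1.0 - w_red) * _gauss(grid, 455.0, 30.0)
             + amp * w_red / (1.0 + np.exp(-(grid - 600.0) / 14.0)))
        refl.append(np.clip(r, 0.0, 1.0))
    return ColourSampleSet("tm30_99ces", grid, np.vstack(refl))


# ---------------------------------------------------------------------------
# public lookup
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=None)
def _observer(name: str) -> ObserverTable:
    if name == "cie1931_2deg":
        _, data = load_packaged_table("cmf_cie1931_2deg_5nm.csv")
    elif name == "cie1964_10deg":
        _, data = load_packaged_table("cmf_cie1964_10deg_10nm.csv")
    else:  # pragma: no cover - guarded by get_table
        raise KeyError(name)
    return ObserverTable(name, data[:, 0], data[:, 1], data[:, 2],
                         data[:, 3])


_TABLE_NAMES = (
    "cie1931_2deg", "cie1964_10deg", "vlambda", "vprime",
    "action_spectra", "illuminants", "cie13_3_8tcs", "tm30_99ces",
)


def get_table(name: str, step_nm: float = 1.0):
    """Return a standard table resampled to the 380–780 nm grid.

    Valid names: cie1931_2deg, cie1964_10deg, vlambda, vprime,
    action_spectra, illuminants, cie13_3_8tcs, tm30_99ces.
    """
    grid = standard_grid(step_nm)
    if name in ("cie1931_2deg", "cie1964_10deg"):
        return _observer(name).resampled(grid)
    if name == "vlambda":
        # V(lambda) is by definition the ybar column of the 1931 observer
        obs = _observer("cie1931_2deg").resampled(grid)
        return np.column_stack([obs.wavelengths, obs.ybar])
    if name == "vprime":
        _, data = load_packaged_table("vprime_scotopic_5nm.csv")
        return np.column_stack([grid, _interp(grid, data[:, 0], data[:, 1])])
    if name == "action_spectra":
        return _action_spectra_1nm().resampled(grid)
    if name == "illuminants":
        return _illuminant_library()
    if name == "cie13_3_8tcs":
        return _tcs8_synthetic().resampled(grid)
    if name == "tm30_99ces":
        return _ces99_synthetic().resampled(grid)
    raise KeyError(
        f"unknown table {name!r}; valid names: " + ", ".join(_TABLE_NAMES))
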