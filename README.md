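# spdcalc

Photometric, colorimetric, colour-fidelity and α-opic calculations for
spectroradiometric measurements, with a URL-safe spectral compression
codec for sharing spectra.

## Who this is for

Light and circadian researchers, lighting engineers and chronobiologists
routinely measure a spectral power distribution *S*(λ) — irradiance in
W/m²/nm or radiance in W/m²/sr/nm — and need the derived quantities that
standards bodies define on top of it. `spdcalc` takes a CSV of one or
more spectra and computes, per spectrum:

* **Photometry** — illuminance [lx] or luminance [cd/m²]:
  683 lm/W · Σ *S*(λ)·*V*(λ)·Δλ.
* **Chromaticity** — CIE 1931 (x, y), CIE 1964 (x₁₀, y₁₀), CIE 1960 UCS
  (u, v) and CIE 1976 UCS (u′, v′), from tristimulus integrals
  X = Σ *S*(λ)·x̄(λ)·Δλ (and likewise Y, Z).
* **Correlated colour temperature** T_cp by two methods — Robertson's
  isotemperature-line interpolation and Ohno's Planckian-table search —
  plus the signed distance D_uv from the Planckian locus. Following the
  standard definition of CCT, both are reported as `N/A` when
  |D_uv| > 0.05.
* **Colour fidelity** — the CIE 2017 colour fidelity index R_f
  (99 evaluation samples, CAM02-UCS colour differences, cf = 6.73,
  R_f = 10·ln(exp(R_f′/10)+1)) and the legacy general colour rendering
  index R_a (8 samples, CIE 1964 U\*V\*W\* with von Kries adaptation,
  per-sample rounding to whole numbers). Optional TM-30 quantities:
  R_f, gamut index R_g, bin-1 chroma shift R_cs,h1, local fidelity
  R_f,h1 and the 16-bin colour vector graphic.
* **α-opic quantities** — for the five human photoreceptor classes
  (S/M/L cones, rods, melanopsin): α-opic (ir)radiance E_α [mW/m²],
  equivalent daylight (il)luminance EDI_α = E_α / ELR_α^D65, and
  efficacy of luminous radiation ELR_α = E_α / illuminance [mW/lm].
  These quantify the non-visual, ipRGC-mediated drive of a light
  exposure (melanopic EDI being the headline number in circadian
  lighting work).

The **spdurl codec** serialises a spectrum into a compact URL-safe
string (`spd1,<start>,<step>,<unit>,<exponent>,<mantissas>[,metadata]`):
a shared exponent with base 2^(1/4), 12-bit γ = 2 gamma-encoded
mantissas, two base64url characters per band. A 36-band spectrum fits
in 89 bytes; a 401-band 1 nm spectrum fits comfortably inside the 2 kB
URL budget browsers tolerate.

> **Note on reference data.** Tables with an exact analytic definition
> (Planckian radiators, Illuminant A, daylight phases) are generated
> from their formulas, and classic published tabulations (1931/1964
> observers, V′(λ), S0/S1/S2, Illuminant C) are vendored as plain-text
> files. The F/FL3/HP/LED illuminant series, the 8 + 99 reflectance
> sample sets and the cone/melanopsin sensitivities are clearly-labelled
> *synthetic stand-ins* with the right structure but not the official
> numbers; see `docs/methods.md` before comparing absolute R_a/R_f or
> α-opic values against other tools.

## Worked example

```python
from spdcalc import (SyntheticSpec, generate, luminous_quantity,
                     tristimulus, chromaticity, cct_ohno,
                     colour_fidelity_rf, colour_rendering_ra)
from spdcalc.alpha_opic import alpha_opic_set

# a warm phosphor-LED-like source: blue pump + broad phosphor band
led = generate(SyntheticSpec("gaussian_led",
                             {"bands": [(450, 20, 1.0), (575, 100, 2.6)],
                              "scale": 0.01}))
print(luminous_quantity(led))            # 1310.22 lx
print(cct_ohno(led).cct_K)               # 3635.5 K
print(colour_rendering_ra(led)[0])       # 52.88
print(colour_fidelity_rf(led)[0])        # 63.65
print(alpha_opic_set(led).edi["mel"])    # 465.75 lx melanopic EDI
```

Output (abridged):

```
illuminance      1310.22 lx
chromaticity     x=0.4232, y=0.4601
CCT (Ohno)       3635.5 K   (Robertson 3635.5 K)   Duv +0.0238
Ra               52.88
Rf (CIE 224)     63.65
melanopic EDI    465.75 lx
melanopic ELR    0.5603 mW/lm
```

Read: this source delivers 1310 lx, appears warm-white (3636 K) but
sits well above the blackbody locus (D_uv +0.024, a greenish tint); its
colour rendering is poor (R_a 53, R_f 64 — the two Gaussians leave deep
spectral gaps), and per lux it provides only 466/1310 ≈ 0.36 as much
melanopic drive as an equally bright daylight would.

The same pipeline is available from the shell:

```sh
spdcalc report measurements.csv --out report.csv        # full report CSV
spdcalc report measurements.csv --tm30 --intermediates  # + CVG images
spdcalc share measurements.csv                          # spdurl share URLs
spdcalc decode "spd1,380,10,wi,4,uJuI..."               # back to CSV
spdcalc fixtures --family planckian -p T=2856           # test spectra
```

`report` accepts up to 5 spectra per file by default; `--power` removes
the cap (batch results are identical to computing each spectrum alone).
Console output is truncated to 4 decimals for display; the written CSV
always carries full double precision.

## Layout

```
src/spdcalc/
  spectrum.py        exact-grid Spectrum / SpectrumBatch containers
  spectra_io.py      CSV parsing, validation, resampling, report writer
  reference_data.py  observers, action spectra, illuminants, samples
  colorimetry.py     tristimulus, photometry, chromaticity systems
  cct.py             Robertson + Ohno CCT, Duv, Planckian tables
  alpha_opic.py      alpha-opic (ir)radiance, EDI/EDL, ELR
  ciecam02.py        CIECAM02 forward model + CAM02-UCS
  fidelity.py        Ra, Rf, TM-30, CVG export
  spdurl.py          the URL-safe codec
  synthetic.py       deterministic fixture generators
  cli.py             click-based command line
```
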