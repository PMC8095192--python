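# Methods

This note documents the models, numerical choices and limitations of
`spdcalc` at the level of detail a user comparing results against other
calculation tools will need.

## Spectra and integration

A spectrum is a uniformly sampled per-nm density on a wavelength grid
stored as integers in 0.1 nm units. Integer grids make uniformity and
equality checks exact; float grids (e.g. `arange(380, 780.1, 0.1)`)
produce spurious spacing differences at the 1e-13 level that would
otherwise surface as parse errors or silent mismatches.

All weighted integrals use rectangular (label-point) summation,
Σ f(λ)·Δλ, with standard tables linearly interpolated onto the
spectrum's grid and set to zero outside their native span. This is the
convention of the spreadsheet-style reference calculators; against
trapezoidal integration the difference is below 0.1 % at 5 nm spacing
for smooth spectra. The calculation span is fixed at 380–780 nm;
narrower inputs are zero-padded with a logged warning, because results
computed from a truncated SPD can carry significant errors.

The photometric constant is exactly 683 lm/W. The photopic V(λ) is by
definition the ȳ column of the 1931 2° observer, so illuminance always
equals 683·Y identically (one code path, not an approximation).

## Reference data: vendored, analytic, synthetic

Three provenance classes, deliberately kept distinct:

1. **Vendored published tabulations** (plain-text CSV under
   `spdcalc/data/`, each with a provenance header): CIE 1931 2° CMFs
   (5 nm), CIE 1964 10° CMFs (10 nm), scotopic V′(λ) (5 nm), daylight
   characteristic vectors S0/S1/S2 (10 nm), Illuminant C (10 nm).
   Finer grids are obtained by linear interpolation, never
   extrapolation.
2. **Analytic constructions**: Planckian radiators (Planck's law with
   c2 = 1.4388×10⁻² m·K; using the older 1.4380×10⁻² value shifts CCT
   results by order 1 K), Illuminant A (blackbody at 2848 K under the
   historical c2, i.e. 2855.54 K under the current one, normalised to
   100 at 560 nm), and daylight phases D(T) = S0 + M1·S1 + M2·S2 with
   xD from the CIE daylight-locus polynomial,
   yD = −3.000 xD² + 2.870 xD − 0.275, and M1, M2 rounded to three
   decimals. D50/D65/D75 are reconstituted at T·(1.4388/1.4380); the
   reconstruction closes on the locus chromaticity to ~1×10⁻⁴.
   Daylight phases are only defined for 4000–25000 K and the bound is
   enforced, not clamped: below 4000 K callers must use a Planckian
   reference.
3. **Synthetic stand-ins**, used where the official tabulation is a
   licensed or unavailable dataset: the F1–F12 / FL3.1–3.15 fluorescent
   series (mercury lines at 404.7/435.8/546.1/577 nm plus halophosphate
   or tri-band phosphor Gaussians parameterised by nominal CCT), HP1–5
   discharge lamps, the LED-B/BH/RGB/V series (Gaussian pump + phosphor
   mixtures), the 8 colour-rendering test samples and 99 colour-
   evaluation samples (smooth hue/chroma-diverse reflectance families,
   75 single-band + 24 blue+red two-band members), and the cone and
   melanopsin sensitivities (Govardovskii A1 photopigment nomograms
   placed at the corneal peak wavelengths 448/542/568/490 nm,
   unit-peak). The rhodopic sensitivity is the vendored V′(λ)
   normalised to unit peak on the grid.

   Consequence: quantities that depend only on *structure* — validity
   rules, self-reference identities, monotonicities, codec behaviour,
   dual-implementation agreement — are unaffected, and that is what the
   test suite asserts. Absolute R_a/R_f values for a given lamp, or
   α-opic ELR constants, will differ from tools using the official
   sample sets and sensitivities and should not be compared across
   tools. The D65 ELR normalisation constants are computed from these
   tables at build time and frozen at 15 significant digits
   (`_d65_constants.py`), so EDI outputs are bit-for-bit reproducible;
   a test asserts the frozen values match recomputation to 6
   significant digits.

## CCT and Duv

**Ohno method** (default): a Planckian (T, u, v) table from 1000 to
100000 K at a geometric step of 0.25 % (the coarser 1 % table is
available via the table parameters, since step size measurably moves
Duv in the 4th decimal); nearest-row search; triangular solution for
the signed Duv; parabolic fit of the three nearest distances for T.
Near the locus (|Duv| < 0.002) the triangular T estimate is used, as
the parabola becomes ill-conditioned there. The Duv sign is positive
above the locus (larger v). Self-recovery of generator temperatures
2000–10000 K is better than 0.1 % with |Duv| < 1×10⁻⁵.

**Robertson method**: the classic 31 isotemperature lines at mireds
0, 10, …, 100, 125, …, 600, interpolated in reciprocal megakelvin. The
rows (u, v, isotherm slope) are computed at import from this package's
own Planckian locus by numerical differentiation rather than vendored,
so both methods share one locus and agree within ~2 K on Planckian
inputs; against the historical printed table (computed with
c2 = 1.4380×10⁻²) small differences are expected.

Both results carry the Ohno Duv, and the single validity rule
|Duv| ≤ 0.05; invalid CCTs render as the literal `N/A` in every output.
The Duv value itself remains numeric in reports (it is well-defined for
any chromaticity).

## Colour fidelity

* **R_a**: Robertson CCT selects the reference (Planckian < 5000 K,
  daylight at/above — the hard switch of the legacy procedure);
  renderings with the 1931 2° observer; 1964 U\*V\*W\* coordinates
  about the reference white; von Kries chromatic-adaptation correction
  of the test renderings; R_i = 100 − 4.6·ΔE_i rounded to the nearest
  whole number before averaging, so R_a is a mean of integers.
* **R_f**: source resampled to 1 nm over 380–780 nm; Ohno CCT;
  reference blends Planckian→daylight linearly between 4000 and 5000 K
  (equal weights at 4500 K), components normalised to equal tristimulus
  Y before mixing; renderings with the 1964 10° observer; CAM02-UCS
  differences; cf = 6.73; R_f = 10·ln(exp((100 − cf·mean ΔE)/10) + 1).
  Every subindex is rounded to 15 significant digits before reuse — a
  cross-implementation reproducibility measure whose numerical effect
  is below 1×10⁻⁶.
* **TM-30**: identical machinery with blend knees 4500/5500 K; the 99
  samples are assigned to 16 fixed 22.5° hue bins by their *reference*
  hue angle; R_g is 100 × the ratio of the shoelace areas of the test
  and reference bin-mean (a′, b′) polygons; R_cs,h1 projects the bin-1
  mean chroma shift on the bin-centre direction and normalises by the
  bin's mean reference chroma; the CVG polygons are normalised so the
  reference bin means lie on the unit circle. The boundary case
  |Duv| = 0.05 is treated as valid everywhere, for consistency across
  the three index families.

**CIECAM02** uses the standard forward model with fidelity viewing
conditions: adapting luminance L_A = 100 cd/m², background Y_b = 20,
average surround, full adaptation D = 1 (conditions are exposed for
research use but these defaults are locked for index calculations).
The Hunt–Pointer–Estévez matrix rows are normalised to sum exactly to
1 so that a stimulus equal to the adopted white maps to a′ = b′ = 0
identically (the published 5-decimal entries sum to 1.00001 on the
first row). The achromatic degenerate case t = 0 takes its explicit
limit C = M = 0 rather than propagating NaN.

## spdurl codec

Shared-exponent base b = 2^(1/4): the minimal integer e with
max(v)/bᵉ ≤ 1 is chosen, costing 1/8 bit of quantisation on average
versus 1/2 bit for base 2; exponents of any size simply serialise to
more decimal digits. Mantissas are m = round(4095·(v/bᵉ)^(1/2)) —
rounding, not truncation, to avoid quantisation bias — and written as
exactly two URL-safe base64 characters per band, high 6 bits first, no
padding. Reconstruction is v = bᵉ·(m/4095)². The worst-case relative
error for bands ≥ 1 % of the maximum is ≲ 0.2 %. Records re-encode
byte-identically (mantissas pass through verbatim), and the value-level
round trip (decode to band values, re-quantise) is also byte-stable
because the γ = 2 grid maps each representable value back to its own
mantissa. Metadata (name/date/timezone/location, single-letter tags
n/d/t/l, percent-encoded) is appended only while the string stays
within the pragmatic 2048-byte URL budget. The unit dictionary holds
30 per-nm codes; `wi` (W/m²/nm) and `uwi` (µW/cm²/nm) are fixed
anchors, the remainder are this package's documented extension, and
distinct codes are never silently converted.

## CSV dialect and report precision

Comma separator, `.` decimal, optional single header row auto-detected
by a non-numeric first cell. The parser never reorders, deduplicates or
interpolates; repairs are explicit `resample` calls. Negative values
(instrument noise) are accepted with a warning and propagate
arithmetically. Report CSVs carry full double precision (`repr`-level,
round-trip exact); 4-decimal truncation and optional exponential
notation are display-layer choices only. The default cap of 5 spectra
per run is this package's declared choice; power mode removes it and
guarantees results identical to spectrum-at-a-time computation.

## Problem sizes and determinism

The test suite and acceptance script run on the standard 401-point 1 nm
grid; the batch-scale check uses 100 synthetic spectra through the full
report pipeline (a few seconds). Everything is deterministic; the only
seeded path is the optional noise injection in the fixture generators
(σ default 0).

## Known limitations

* Synthetic stand-in tables (above) — structural fidelity, not
  standards-exact values; absolute indices are not comparable across
  tools.
* No observer models beyond the 2° and 10° CMFs; no age- or field-size
  dependent α-opic corrections; no retinal-irradiance conversion.
* CCT is not defined above 100000 K (table upper bound).
* TM-30 output is limited to R_f, R_g, R_cs,h1, R_f,h1 and the CVG; the
  full 16-bin vectors and annex design tools are out of scope.
* The codec implements only the 12-bit mantissa format; the historical
  18-bit variant is not supported.
* Vendored tables are transcriptions of the classic abridged
  tabulations; the 1964 observer is tabulated at 10 nm and interpolated.
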