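"""URL-safe spectral power distribution codec ("spdurl").

Format (one line, comma-separated fields)::

    spd1,<start_nm>,<step_nm>,<unit>,<exponent>,<mantissas>[,<metadata>...]

* ``spd1`` — version tag.
* start/step — uniform wavelength grid origin and spacing in nm.
* unit — required 2–3 character shorthand from :data:`UNITS` (per-nm
  spectral units; e.g. ``wi`` = W/m²/nm, ``uwi`` = µW/cm²/nm).
* exponent — signed decimal integer e; all band values share the scale
  b**e with base b = 2**(1/4).  The quarter-power base sacrifices 1/8
  bit to quantisation on average instead of the 1/2 bit a base of 2
  would cost; large exponents simply use more decimal bytes.
* mantissas — each band value v is gamma-encoded (γ = 2) to a 12-bit
  integer m = round(4095·(v/b**e)**(1/γ)) and written as exactly two
  URL-safe base64 characters (RFC 4648 §5 alphabet), high 6 bits first,
  no padding.  Rounding (not truncation) avoids quantisation bias.
* metadata — optional percent-encoded fields tagged by a single letter:
  n=name, d=date, t=timezone, l=location.  Appended only while the
  total string stays within the 2048-byte URL budget that browsers
  enforce in practice.
"""

from __future__ import annotations

import math
import urllib.parse
from dataclasses import dataclass, field

import numpy as np

from .spectrum import Mode, Spectrum

__all__ = [
    "UNITS", "BASE", "GAMMA", "MAX_URL_BYTES", "SpdUrlError",
    "SpdUrlRecord", "encode", "decode", "encode_spectrum", "record_values",
    "record_to_spectrum", "share_url",
]

BASE = 2.0 ** 0.25
GAMMA = 2.0
MAX_URL_BYTES = 2048
_ALPHABET = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
             "abcdefghijklmnopqrstuvwxyz0123456789-_")
_CHAR_INDEX = {c: i for i, c in enumerate(_ALPHABET)}

#: Per-nm spectral unit shorthands.  "wi" and "uwi" are fixed anchors;
#: the remaining codes are this package's documented extension.
UNITS: dict[str, str] = {
    "wi": "W/m^2/nm", "mwi": "mW/m^2/nm", "uwi": "uW/cm^2/nm",
    "wci": "W/cm^2/nm", "mci": "mW/cm^2/nm", "umi": "uW/m^2/nm",
    "wr": "W/m^2/sr/nm", "mwr": "mW/m^2/sr/nm", "uwr": "uW/cm^2/sr/nm",
    "wcr": "W/cm^2/sr/nm", "mcr": "mW/cm^2/sr/nm", "umr": "uW/m^2/sr/nm",
    "qi": "quanta/cm^2/s/nm", "qr": "quanta/cm^2/s/sr/nm",
    "mqi": "Mquanta/cm^2/s/nm", "mqr": "Mquanta/cm^2/s/sr/nm",
    "pi": "photons/m^2/s/nm", "pr": "photons/m^2/s/sr/nm",
    "li": "lm/m^2/nm", "lr": "lm/m^2/sr/nm",
    "eni": "umol/m^2/s/nm", "enr": "umol/m^2/s/sr/nm",
    "rel": "relative/nm", "act": "action spectrum (unit peak)/nm",
    "tr": "transmittance/nm", "ref": "reflectance/nm", "abs": "absorbance/nm",
    "ci": "counts/nm", "cr": "counts/sr/nm", "pct": "percent/nm",
}

_META_TAGS = {"n": "name", "d": "date", "t": "timezone", "l": "location"}
_TAG_BY_FIELD = {v: k for k, v in _META_TAGS.items()}


class SpdUrlError(ValueError):
    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"{code}: {message}")


@dataclass(frozen=True)
class SpdUrlRecord:
    """Decoded in-memory form of an spdurl string."""

    start_nm: float
    step_nm: float
    unit_code: str
    exponent: int
    mantissas: tuple[int, ...]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.unit_code not in UNITS:
            raise SpdUrlError("E_SPD_UNIT",
                              f"unknown unit code {self.unit_code!r}")
        if any(not (0 <= m <= 4095) for m in self.mantissas):
            raise SpdUrlError("E_SPD_RANGE", "mantissa outside 0..4095")


def _fmt_num(x: float) -> str:
    return f"{x:g}"


def _choose_exponent(vmax: float) -> int:
    """Minimal integer e with vmax / BASE**e <= 1."""
    if vmax <= 0.0:
        return 0
    e = math.ceil(math.log(vmax) / math.log(BASE) - 1e-12)
    while BASE ** e < vmax:
        e += 1
    while e > math.log(vmax) / math.log(BASE) + 1:  # pragma: no cover
        e -= 1
    return int(e)


def _quantise(values: np.ndarray, exponent: int) -> list[int]:
    scaled = np.clip(values / BASE ** exponent, 0.0, 1.0)
    return [int(m) for m in np.rint(4095.0 * scaled ** (1.0 / GAMMA))]


def encode(record_or_spectrum, unit: str | None = None,
           metadata: dict[str, str] | None = None,
           clamp_negative: bool = False) -> str:
    """Encode a :class:`SpdUrlRecord` or a :class:`Spectrum` to a string.

    Encoding a record is exact (the mantissas are written verbatim), so
    decode→encode round-trips byte-identically.  Encoding a spectrum
    quantises its values first.
    """
    if isinstance(record_or_spectrum, SpdUrlRecord):
        rec = record_or_spectrum
        if metadata:
            rec = SpdUrlRecord(rec.start_nm, rec.step_nm, rec.unit_code,
                               rec.exponent, rec.mantissas,
                               {**rec.metadata, **metadata})
    else:
        rec = _record_from_spectrum(record_or_spectrum, unit,
                                    metadata or {}, clamp_negative)

    mant = "".join(
        _ALPHABET[m >> 6] + _ALPHABET[m & 0x3F] for m in rec.mantissas)
    core = ",".join([
        "spd1", _fmt_num(rec.start_nm), _fmt_num(rec.step_nm),
        rec.unit_code, str(rec.exponent), mant,
    ])
    if len(core) > MAX_URL_BYTES:
        raise SpdUrlError(
            "E_SPD_TOOLONG",
            f"encoded form is {len(core)} bytes, over the {MAX_URL_BYTES} "
            "byte URL budget; meters with high spectral resolution may "
            "wish to resample to fewer bands before encoding")
    out = core
    for fieldname, tag in _TAG_BY_FIELD.items():
        if fieldname in rec.metadata:
            piece = "," + tag + urllib.parse.quote(rec.metadata[fieldname],
                                                   safe="")
            if len(out) + len(piece) <= MAX_URL_BYTES:
                out += piece
    return out


def _record_from_spectrum(spectrum: Spectrum, unit: str | None,
                          metadata: dict[str, str],
                          clamp_negative: bool) -> SpdUrlRecord:
    if unit is None:
        unit = "wi" if spectrum.mode is Mode.IRRADIANCE else "wr"
    values = np.asarray(spectrum.values, float)
    if np.any(values < 0):
        if not clamp_negative:
            raise SpdUrlError("E_SPD_NEGATIVE",
                              "negative band values cannot be encoded; "
                              "pass clamp_negative=True to clamp to zero")
        values = np.clip(values, 0.0, None)
    exponent = _choose_exponent(float(values.max(initial=0.0)))
    mantissas = tuple(_quantise(values, exponent))
    return SpdUrlRecord(spectrum.start_nm, spectrum.step_nm, unit,
                        exponent, mantissas, metadata)


def encode_spectrum(spectrum: Spectrum, unit: str | None = None,
                    **kwargs) -> str:
    return encode(spectrum, unit=unit, **kwargs)


def decode(text: str) -> SpdUrlRecord:
    """Decode an spdurl string; raises :class:`SpdUrlError` on corruption."""
    fields = text.strip().split(",")
    if not fields or fields[0] != "spd1":
        raise SpdUrlError("E_SPD_VERSION",
                          f"bad version tag {fields[0] if fields else ''!r}")
    if len(fields) < 6:
        raise SpdUrlError("E_SPD_LENGTH", "missing header fields")
    try:
        start_nm = float(fields[1])
        step_nm = float(fields[2])
    except ValueError as exc:
        raise SpdUrlError("E_SPD_HEADER", f"bad wavelength field: {exc}")
    unit_code = fields[3]
    if unit_code not in UNITS:
        raise SpdUrlError("E_SPD_UNIT", f"unknown unit code {unit_code!r}")
    try:
        exponent = int(fields[4])
    except ValueError:
        raise SpdUrlError("E_SPD_HEADER", f"bad exponent field {fields[4]!r}")

    mant = fields[5]
    if len(mant) % 2 != 0:
        raise SpdUrlError("E_SPD_LENGTH",
                          f"mantissa field length {len(mant)} is odd")
    mantissas = []
    for i in range(0, len(mant), 2):
        hi, lo = mant[i], mant[i + 1]
        if hi not in _CHAR_INDEX or lo not in _CHAR_INDEX:
            raise SpdUrlError("E_SPD_CHAR",
                              f"non-base64url character at position {i}")
        mantissas.append((_CHAR_INDEX[hi] << 6) | _CHAR_INDEX[lo])

    metadata: dict[str, str] = {}
    for extra in fields[6:]:
        if not extra:
            continue
        tag, value = extra[0], extra[1:]
        if tag in _META_TAGS:
            metadata[_META_TAGS[tag]] = urllib.parse.unquote(value)
    return SpdUrlRecord(start_nm, step_nm, unit_code, exponent,
                        tuple(mantissas), metadata)


def record_values(record: SpdUrlRecord) -> np.ndarray:
    """Reconstruct band values: v = b**e · (m/4095)**γ."""
    m = np.asarray(record.mantissas, float)
    return BASE ** record.exponent * (m / 4095.0) ** GAMMA


def record_to_spectrum(record: SpdUrlRecord,
                       mode: Mode | None = None) -> Spectrum:
    if mode is None:
        mode = (Mode.RADIANCE if "sr" in UNITS[record.unit_code]
                else Mode.IRRADIANCE)
    return Spectrum.from_nm(record.start_nm, record.step_nm,
                            record_values(record), mode,
                            label=record.metadata.get("name", "spdurl"))


def share_url(record_or_spectrum, base: str = "https://luox.app",
              **kwargs) -> str:
    """Platform share URL: ``<base>/u/<encoded string>``."""
    prefix = base.rstrip("/") + "/u/"
    encoded = encode(record_or_spectrum, **kwargs)
    url = prefix + encoded
    if len(url) > MAX_URL_BYTES:
        raise SpdUrlError(
            "E_SPD_TOOLONG",
            f"share URL is {len(url)} bytes; many web browsers truncate "
            f"URLs beyond {MAX_URL_BYTES} bytes (2 kB)")
    return url
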