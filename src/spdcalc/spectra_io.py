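"""CSV parsing, validation, resampling and report writing.

Input dialect (documented here, bit-exactly): comma separator, ``.``
decimal point, UTF-8, LF or CRLF line endings; first column is the
wavelength in nm, every further column one spectrum; one optional header
row, auto-detected by a non-numeric first cell.  Wavelengths must be
strictly increasing and exactly uniformly spaced on a 0.1 nm integer
grid.  The parser never silently reorders, deduplicates or interpolates
— any repair is an explicit :func:`resample` call.

Validation failures raise :class:`CsvFormatError` with a machine-usable
error code (E_SPACING, E_NUMERIC, E_COLUMNS, E_ROWS) and a row/column
address, mirroring indicative upload error messages.
"""

from __future__ import annotations

import csv
import io
import logging
import warnings

import numpy as np

from .spectrum import Mode, Spectrum, SpectrumBatch, STANDARD_SPAN_NM

__all__ = [
    "CsvFormatError",
    "parse_spectrum_csv",
    "write_spectrum_csv",
    "write_report_csv",
    "resample",
]

log = logging.getLogger("spdcalc")


class CsvFormatError(ValueError):
    """A CSV validation failure with an error code and cell address."""

    def __init__(self, code: str, message: str, row: int | None = None,
                 col: int | None = None):
        self.code = code
        self.row = row
        self.col = col
        where = ""
        if row is not None:
            where = f" (row {row}" + (f", column {col}" if col else "") + ")"
        super().__init__(f"{code}: {message}{where}")


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def parse_spectrum_csv(text: str, mode: Mode | str = Mode.IRRADIANCE
                       ) -> SpectrumBatch:
    """Parse CSV text into a batch of spectra sharing one grid.

    Raises :class:`CsvFormatError` on nonuniform spacing (E_SPACING),
    non-numeric or blank cells (E_NUMERIC), missing data columns
    (E_COLUMNS) or fewer than two data rows (E_ROWS).
    """
    mode = Mode(mode)
    rows = [r for r in csv.reader(io.StringIO(text)) if any(c.strip() for c in r)]
    if not rows:
        raise CsvFormatError("E_ROWS", "file contains no data")

    labels: list[str] | None = None
    if not _is_number(rows[0][0]):
        labels = [c.strip() for c in rows[0][1:]]
        rows = rows[1:]

    if not rows:
        raise CsvFormatError("E_ROWS", "too few samples: no data rows")
    width = len(rows[0])
    if width < 2:
        raise CsvFormatError("E_COLUMNS", "no data columns after wavelength",
                             row=1)
    if labels is None:
        labels = [f"S{i}" for i in range(1, width)]
    elif len(labels) != width - 1:
        raise CsvFormatError("E_COLUMNS",
                             f"header has {len(labels)} labels for "
                             f"{width - 1} data columns", row=1)

    data = np.empty((len(rows), width))
    for i, row in enumerate(rows, start=1):
        if len(row) != width:
            raise CsvFormatError("E_COLUMNS",
                                 f"expected {width} cells, found {len(row)}",
                                 row=i)
        for j, cell in enumerate(row, start=1):
            cell = cell.strip()
            if not cell or not _is_number(cell):
                raise CsvFormatError("E_NUMERIC",
                                     f"non-numeric cell {cell!r}",
                                     row=i, col=j)
            data[i - 1, j - 1] = float(cell)
    if not np.all(np.isfinite(data)):
        raise CsvFormatError("E_NUMERIC", "non-finite value in data")

    if len(rows) < 2:
        raise CsvFormatError("E_ROWS", "too few samples: need at least 2 rows")

    wl = data[:, 0]
    dnm = np.round(wl * 10.0)
    if np.max(np.abs(dnm - wl * 10.0)) > 1e-6:
        bad = int(np.argmax(np.abs(dnm - wl * 10.0))) + 1
        raise CsvFormatError("E_SPACING",
                             "wavelengths must lie on a 0.1 nm grid",
                             row=bad)
    dnm = dnm.astype(int)
    steps = np.diff(dnm)
    if np.any(steps <= 0):
        bad = int(np.argmax(steps <= 0)) + 2
        raise CsvFormatError("E_SPACING",
                             "wavelengths must be strictly increasing",
                             row=bad)
    if np.any(steps != steps[0]):
        bad = int(np.argmax(steps != steps[0])) + 2
        raise CsvFormatError("E_SPACING", "nonuniform spacing", row=bad)

    if np.any(data[:, 1:] < 0):
        warnings.warn("negative spectral values present (instrument noise?); "
                      "they propagate arithmetically", stacklevel=2)
    lo, hi = STANDARD_SPAN_NM
    if wl[0] > lo or wl[-1] < hi:
        log.warning(
            "input covers %.0f-%.0f nm, narrower than the %g-%g nm "
            "calculation span; missing wavelengths are treated as zero and "
            "calculated results may have significant errors",
            wl[0], wl[-1], lo, hi)

    spectra = [
        Spectrum(int(dnm[0]), int(steps[0]), data[:, j + 1], mode,
                 label=labels[j])
        for j in range(width - 1)
    ]
    return SpectrumBatch(spectra)


def write_spectrum_csv(batch: SpectrumBatch | Spectrum) -> str:
    """Write spectra back to CSV (full double precision, round-trips)."""
    if isinstance(batch, Spectrum):
        batch = SpectrumBatch([batch])
    lines = ["wavelength_nm," + ",".join(s.label for s in batch)]
    wl = batch.wavelengths
    for i, w in enumerate(wl):
        cells = [f"{w:g}"] + [repr(float(s.values[i])) for s in batch]
        lines.append(",".join(cells))
    return "\n".join(lines) + "\n"


def write_report_csv(results: list[tuple[str, list]],
                     notation: str = "linear") -> str:
    """Serialise report rows to CSV at full double precision.

    ``results`` is a list of (quantity label, per-spectrum values); a
    value may be a float or the literal string "N/A".  Exponential
    notation is an opt-in display choice; either way the file carries
    repr-level precision and round-trips exactly.
    """
    def fmt(v) -> str:
        if isinstance(v, str):
            return v
        v = float(v)
        if notation == "exponential":
            return f"{v:.17e}"
        return repr(v)

    lines = []
    for label, values in results:
        lines.append(",".join(['"' + label + '"'] + [fmt(v) for v in values]))
    return "\n".join(lines) + "\n"


def resample(spectrum: Spectrum, new_step_nm: float,
             span: tuple[float, float] = STANDARD_SPAN_NM) -> Spectrum:
    """Linear interpolation onto a new uniform grid over ``span``.

    Interpolation acts on the per-nm density values (no rebinning
    factor); outside the spectrum's native span the result is zero.
    """
    lo, hi = span
    n_steps = (hi - lo) / new_step_nm
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"step {new_step_nm} nm does not divide the span "
                         f"{lo}-{hi} nm")
    if spectrum.end_nm < lo or spectrum.start_nm > hi:
        raise ValueError("spectrum does not overlap the requested span")
    grid = lo + new_step_nm * np.arange(int(round(n_steps)) + 1)
    vals = np.interp(grid, spectrum.wavelengths, spectrum.values,
                     left=0.0, right=0.0)
    return Spectrum.from_nm(lo, new_step_nm, vals, spectrum.mode,
                            spectrum.label)
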