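"""Low-level readers/writers for the package's plain-text data tables.

Format: CSV with any number of leading comment lines starting with ``#``
(provenance header), then one header row of column names, then numeric
rows.  The writer emits exactly what the reader accepts so every vendored
table round-trips byte-identically.
"""

from __future__ import annotations

import io
from importlib import resources

import numpy as np

__all__ = ["read_table", "write_table", "load_packaged_table"]


def read_table(text: str) -> tuple[list[str], list[str], np.ndarray]:
    """Parse a table; returns (comment_lines, column_names, data)."""
    comments: list[str] = []
    names: list[str] | None = None
    rows: list[list[float]] = []
    for line in text.splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            if names is not None:
                raise ValueError("comment lines must precede the header")
            comments.append(line)
        elif names is None:
            names = [c.strip() for c in line.split(",")]
        else:
            rows.append([float(c) for c in line.split(",")])
    if names is None or not rows:
        raise ValueError("table has no data")
    data = np.asarray(rows, dtype=float)
    if data.shape[1] != len(names):
        raise ValueError("ragged table")
    return comments, names, data


def write_table(comments: list[str], names: list[str], data: np.ndarray,
                cell_format: str = "{:g}") -> str:
    buf = io.StringIO()
    for c in comments:
        buf.write(c + "\n")
    buf.write(",".join(names) + "\n")
    for row in np.asarray(data):
        buf.write(",".join(cell_format.format(v) for v in row) + "\n")
    return buf.getvalue()


def load_packaged_table(filename: str) -> tuple[list[str], np.ndarray]:
    """Load a table from the package ``data`` directory."""
    text = (resources.files("spdcalc") / "data" / filename).read_text()
    _, names, data = read_table(text)
    return names, data
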