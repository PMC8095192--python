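"""Correlated colour temperature and Duv.

Two CCT solvers are provided:

* Ohno's table-search method: nearest row of a geometric Planckian
  (T, u, v) table, triangular solution for Duv, parabolic refinement of
  T.  Default table: 1000–100000 K at 0.25 % geometric step.
* Robertson's method: interpolation between isotemperature lines in
  reciprocal megakelvin over the classic 31-row mired spacing
  (0, 10, …, 100, 125, …, 600 MK⁻¹).  The rows are computed from this
  package's own Planckian locus rather than vendored.

Both results carry Duv from the Ohno solution and the validity rule
that no CCT is reported when |Duv| > 0.05 (the output shows N/A).
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from .colorimetry import ChromaticityPoint, ChromaticitySystem, spectrum_uv
from .reference_data import planckian_spd, standard_grid
from .spectrum import Spectrum

__all__ = [
    "DUV_VALIDITY_LIMIT",
    "CCTResult",
    "PlanckianTable",
    "build_planckian_table",
    "cct_ohno",
    "cct_robertson",
]

#: |Duv| above this means the chromaticity is too far off the Planckian
#: locus for CCT to be meaningful; all dependent indices report N/A.
DUV_VALIDITY_LIMIT = 0.05


@dataclass(frozen=True)
class CCTResult:
    """CCT in kelvin with Ohno Duv, method tag and the N/A validity flag."""

    cct_K: float
    duv: float
    method: str  # "robertson" | "ohno"
    valid: bool

    def display(self) -> str:
        return f"{self.cct_K:.1f}" if self.valid else "N/A"


@dataclass(frozen=True)
class PlanckianTable:
    """(T, u, v) sampled geometrically along the Planckian locus."""

    T: np.ndarray
    u: np.ndarray
    v: np.ndarray
    step_percent: float


def _locus_uv(T: float, grid: np.ndarray) -> tuple[float, float]:
    pt = spectrum_uv(planckian_spd(T, grid))
    return pt.a, pt.b


@functools.lru_cache(maxsize=8)
def build_planckian_table(t_min: float = 1000.0, t_max: float = 100000.0,
                          step_percent: float = 0.25) -> PlanckianTable:
    """Geometric temperature grid with (u, v) from the Planckian generator."""
    if not (0 < t_min < t_max and step_percent > 0):
        raise ValueError("invalid Planckian table parameters")
    ratio = 1.0 + step_percent / 100.0
    n = int(np.ceil(np.log(t_max / t_min) / np.log(ratio))) + 1
    T = t_min * ratio ** np.arange(n)
    grid = standard_grid(1.0)
    uv = np.array([_locus_uv(t, grid) for t in T])
    return PlanckianTable(T, uv[:, 0], uv[:, 1], step_percent)


def _as_uv(point) -> tuple[float, float]:
    if isinstance(point, Spectrum):
        point = spectrum_uv(point)
    if isinstance(point, ChromaticityPoint):
        if point.system is not ChromaticitySystem.UV_1960:
            raise ValueError("CCT expects a CIE 1960 (u, v) point")
        return point.a, point.b
    u, v = point
    return float(u), float(v)


def cct_ohno(point, table: PlanckianTable | None = None) -> CCTResult:
    """Ohno's method: nearest table row, triangular Duv, parabolic T.

    ``point`` may be a (u, v) pair, a 1960-UCS ChromaticityPoint, or a
    Spectrum (converted with the 2° observer).
    """
    u, v = _as_uv(point)
    if table is None:
        table = build_planckian_table()
    d = np.hypot(table.u - u, table.v - v)
    m = int(np.argmin(d))
    m = min(max(m, 1), len(table.T) - 2)

    tm1, tm, tp1 = table.T[m - 1], table.T[m], table.T[m + 1]
    dm1, dm, dp1 = d[m - 1], d[m], d[m + 1]

    # triangular solution between rows m-1 and m+1
    ell = np.hypot(table.u[m + 1] - table.u[m - 1],
                   table.v[m + 1] - table.v[m - 1])
    x = (dm1**2 - dp1**2 + ell**2) / (2.0 * ell)
    t_tri = tm1 + (tp1 - tm1) * x / ell
    duv_mag = np.sqrt(max(dm1**2 - x**2, 0.0))
    v_x = table.v[m - 1] + (table.v[m + 1] - table.v[m - 1]) * x / ell
    sign = 1.0 if v >= v_x else -1.0
    duv = sign * duv_mag

    # parabolic refinement of T through the three nearest distances
    x1, x2, x3 = tm1, tm, tp1
    denom = (x3 - x2) * (x2 - x1) * (x1 - x3)
    if denom != 0.0:
        a = (x1 * (dp1 - dm) + x2 * (dm1 - dp1) + x3 * (dm - dm1)) / denom
        b = -(x1**2 * (dp1 - dm) + x2**2 * (dm1 - dp1)
              + x3**2 * (dm - dm1)) / denom
        t_par = -b / (2.0 * a) if a != 0.0 else t_tri
    else:  # pragma: no cover - distinct table temperatures guaranteed
        t_par = t_tri
    # near the locus the triangular T is the more stable estimate
    cct = t_tri if abs(duv) < 0.002 else t_par

    valid = abs(duv) <= DUV_VALIDITY_LIMIT
    return CCTResult(float(cct), float(duv), "ohno", bool(valid))


# -- Robertson ---------------------------------------------------------------

_ROBERTSON_MIREDS = tuple(
    list(range(0, 101, 10)) + list(range(125, 601, 25)))  # 31 rows


@functools.lru_cache(maxsize=1)
def _robertson_rows() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(mired, u, v, isotherm slope) computed from the Planckian locus.

    The isotemperature line through each locus point is normal to the
    locus; its slope t = -du/dv is obtained by numerical differentiation
    with respect to temperature.  Mired 0 (infinite T) is approximated
    at 1e8 K, far beyond any practical chromaticity difference.
    """
    grid = standard_grid(1.0)
    mireds = np.array(_ROBERTSON_MIREDS, float)
    T = np.where(mireds == 0.0, 1e8, 1e6 / np.maximum(mireds, 1e-12))
    us, vs, slopes = [], [], []
    for t in T:
        u0, v0 = _locus_uv(t, grid)
        dt = t * 1e-4
        u1, v1 = _locus_uv(t - dt, grid)
        u2, v2 = _locus_uv(t + dt, grid)
        du, dv = u2 - u1, v2 - v1
        us.append(u0)
        vs.append(v0)
        slopes.append(-du / dv if dv != 0 else np.inf)
    return mireds, np.array(us), np.array(vs), np.array(slopes)


def cct_robertson(point, duv: float | None = None) -> CCTResult:
    """Robertson's isotemperature-line interpolation in reciprocal MK.

    The Duv attached to the result (and driving the N/A rule) is taken
    from the Ohno computation, matching the single-Duv output contract.
    """
    u, v = _as_uv(point)
    if duv is None:
        duv = cct_ohno((u, v)).duv

    mireds, ur, vr, tr = _robertson_rows()
    # signed distance from the point to each isotemperature line
    d = ((v - vr) - tr * (u - ur)) / np.sqrt(1.0 + tr**2)

    cct = float("nan")
    for i in range(len(mireds) - 1):
        if d[i] == 0.0:
            cct = 1e6 / mireds[i] if mireds[i] > 0 else 1e8
            break
        if d[i] * d[i + 1] < 0.0:
            frac = d[i] / (d[i] - d[i + 1])
            mired = mireds[i] + frac * (mireds[i + 1] - mireds[i])
            cct = 1e6 / mired if mired > 0 else 1e8
            break

    valid = np.isfinite(cct) and abs(duv) <= DUV_VALIDITY_LIMIT
    return CCTResult(float(cct), float(duv), "robertson", bool(valid))
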