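"""CIECAM02 forward model and the CAM02-UCS uniform colour space.

Only the forward direction is needed for colour-fidelity work: XYZ of a
sample under an adopted white → appearance correlates (J, C, M, h) →
CAM02-UCS coordinates (J′, a′, b′).

Viewing conditions default to the colour-fidelity convention: adapting
luminance L_A = 100 cd/m², background Y_b = 20, average surround
(F = 1, c = 0.69, N_c = 1), full chromatic adaptation D = 1.  The
achromatic degenerate case t = 0 is handled by its explicit limit
(C = M = 0) rather than NaN propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ViewingConditions", "Cam02UcsCoords", "cam02ucs", "CIE224_CONDITIONS"]

_M_CAT02 = np.array([
    [0.7328, 0.4296, -0.1624],
    [-0.7036, 1.6975, 0.0061],
    [0.0030, 0.0136, 0.9834],
])
_M_HPE = np.array([
    [0.38971, 0.68898, -0.07868],
    [-0.22981, 1.18340, 0.04641],
    [0.00000, 0.00000, 1.00000],
])
# Normalise rows to sum exactly to 1 so an achromatic stimulus equal to
# the adopted white maps to a = b = 0 identically (the published
# four-decimal entries sum to 1.00001 on the first row).
_M_HPE = _M_HPE / _M_HPE.sum(axis=1, keepdims=True)


@dataclass(frozen=True)
class ViewingConditions:
    la: float = 100.0        # adapting luminance [cd/m²]
    yb: float = 20.0         # relative background luminance
    surround: str = "average"
    d: float | None = 1.0    # None → compute D from F and la

    @property
    def fcn(self) -> tuple[float, float, float]:
        return {
            "average": (1.0, 0.69, 1.0),
            "dim": (0.9, 0.59, 0.9),
            "dark": (0.8, 0.525, 0.8),
        }[self.surround]


CIE224_CONDITIONS = ViewingConditions()


@dataclass(frozen=True)
class Cam02UcsCoords:
    """CAM02-UCS J′, a′, b′ (arrays over samples) plus raw correlates."""

    jp: np.ndarray
    ap: np.ndarray
    bp: np.ndarray
    J: np.ndarray
    M: np.ndarray
    h_deg: np.ndarray
    conditions: ViewingConditions


def _nonlinear(rgb: np.ndarray, fl: float) -> np.ndarray:
    """Post-adaptation cone response compression (sign-preserving)."""
    x = fl * np.abs(rgb) / 100.0
    t = x ** 0.42
    return np.sign(rgb) * 400.0 * t / (t + 27.13) + 0.1


def cam02ucs(sample_xyz: np.ndarray, white_xyz: np.ndarray,
             conditions: ViewingConditions = CIE224_CONDITIONS) -> Cam02UcsCoords:
    """Forward CIECAM02 + UCS transform for one or more XYZ samples.

    ``sample_xyz`` has shape (3,) or (n, 3); ``white_xyz`` is the adopted
    white with Y normalised to 100.
    """
    xyz = np.atleast_2d(np.asarray(sample_xyz, float))
    if np.any(xyz[:, 1] < 0):
        raise ValueError("negative luminance Y is non-physical")
    xyzw = np.asarray(white_xyz, float)
    if not np.isclose(xyzw[1], 100.0, atol=0.5):
        raise ValueError("white point must be normalised to Y=100")

    f, c, nc = conditions.fcn
    la, yb = conditions.la, conditions.yb
    k = 1.0 / (5.0 * la + 1.0)
    fl = 0.2 * k**4 * 5.0 * la + 0.1 * (1.0 - k**4) ** 2 * (5.0 * la) ** (1.0 / 3.0)
    n = yb / xyzw[1]
    nbb = ncb = 0.725 * (1.0 / n) ** 0.2
    z = 1.48 + np.sqrt(n)

    d = conditions.d
    if d is None:
        d = f * (1.0 - (1.0 / 3.6) * np.exp((-la - 42.0) / 92.0))
    d = float(np.clip(d, 0.0, 1.0))

    rgb_w = _M_CAT02 @ xyzw
    d_rgb = xyzw[1] * d / rgb_w + 1.0 - d
    rgb = xyz @ _M_CAT02.T
    rgb_c = rgb * d_rgb
    rgb_wc = rgb_w * d_rgb

    m_h = _M_HPE @ np.linalg.inv(_M_CAT02)
    rgb_p = rgb_c @ m_h.T
    rgb_wp = m_h @ rgb_wc
    rgb_a = _nonlinear(rgb_p, fl)
    rgb_aw = _nonlinear(rgb_wp, fl)

    ra, ga, ba = rgb_a[:, 0], rgb_a[:, 1], rgb_a[:, 2]
    a = ra - 12.0 * ga / 11.0 + ba / 11.0
    b = (ra + ga - 2.0 * ba) / 9.0
    h = np.degrees(np.arctan2(b, a)) % 360.0

    e_t = 0.25 * (np.cos(np.radians(h) + 2.0) + 3.8)
    A = (2.0 * ra + ga + ba / 20.0 - 0.305) * nbb
    Aw = (2.0 * rgb_aw[0] + rgb_aw[1] + rgb_aw[2] / 20.0 - 0.305) * nbb
    J = 100.0 * np.clip(A / Aw, 0.0, None) ** (c * z)

    denom = ra + ga + 21.0 * ba / 20.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (50000.0 / 13.0 * nc * ncb * e_t * np.hypot(a, b)) / denom
    t = np.where(np.isfinite(t) & (t > 0), t, 0.0)
    C = t**0.9 * np.sqrt(J / 100.0) * (1.64 - 0.29**n) ** 0.73
    M = C * fl**0.25

    jp = 1.7 * J / (1.0 + 0.007 * J)
    mp = np.log1p(0.0228 * M) / 0.0228
    ap = mp * np.cos(np.radians(h))
    bp = mp * np.sin(np.radians(h))

    squeeze = np.asarray(sample_xyz).ndim == 1
    if squeeze:
        jp, ap, bp = jp[0:1], ap[0:1], bp[0:1]
    return Cam02UcsCoords(jp, ap, bp, J, M, h, conditions)
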