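"""Independent second implementations used as cross-check oracles.

Everything here is written directly from the standards' equations as a
separate code path: scalar step-by-step CIECAM02, brute-force CCT by
locus search, and spreadsheet-style Ra / Rf recomputations.  These
functions deliberately share no code with the package (only its data
tables, which are inputs, not algorithms).
"""

from __future__ import annotations

import math

import numpy as np

from spdcalc.reference_data import get_table

C2 = 1.4388e-2


# ---------------------------------------------------------------------------
# basic colorimetry, coded independently (trapezoid-free rectangular sums)
# ---------------------------------------------------------------------------

def oracle_xyz(wl, spd, observer="cie1931_2deg"):
    obs = get_table(observer)
    xb = np.interp(wl, obs.wavelengths, obs.xbar, left=0, right=0)
    yb = np.interp(wl, obs.wavelengths, obs.ybar, left=0, right=0)
    zb = np.interp(wl, obs.wavelengths, obs.zbar, left=0, right=0)
    dl = wl[1] - wl[0]
    return (float((spd * xb).sum() * dl), float((spd * yb).sum() * dl),
            float((spd * zb).sum() * dl))


def oracle_uv(wl, spd):
    X, Y, Z = oracle_xyz(wl, spd)
    den = X + 15 * Y + 3 * Z
    return 4 * X / den, 6 * Y / den


def oracle_planck(wl, T):
    lam = np.asarray(wl) * 1e-9
    return lam ** -5 / np.expm1(C2 / (lam * T))


def oracle_cct_brute(wl, spd, t_lo=1000.0, t_hi=30000.0):
    """CCT by direct minimisation of (u, v) distance to the locus."""
    u0, v0 = oracle_uv(wl, spd)

    def dist(T):
        u, v = oracle_uv(wl, oracle_planck(wl, T))
        return math.hypot(u - u0, v - v0)

    # coarse geometric scan, then golden-section refinement
    ts = np.geomspace(t_lo, t_hi, 400)
    ds = [dist(t) for t in ts]
    i = int(np.argmin(ds))
    lo, hi = ts[max(i - 1, 0)], ts[min(i + 1, len(ts) - 1)]
    phi = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c, d = b - phi * (b - a), a + phi * (b - a)
    for _ in range(60):
        if dist(c) < dist(d):
            b, d = d, c
            c = b - phi * (b - a)
        else:
            a, c = c, d
            d = a + phi * (b - a)
    t_best = 0.5 * (a + b)
    u, v = oracle_uv(wl, oracle_planck(wl, t_best))
    duv = math.copysign(dist(t_best), v0 - v)
    return t_best, duv


# ---------------------------------------------------------------------------
# independent CIECAM02 (scalar, explicit steps)
# ---------------------------------------------------------------------------

_CAT02 = [[0.7328, 0.4296, -0.1624],
          [-0.7036, 1.6975, 0.0061],
          [0.0030, 0.0136, 0.9834]]
# published inverse of the CAT02 matrix
_CAT02_INV = [[1.096124, -0.278869, 0.182745],
              [0.454369, 0.473533, 0.072098],
              [-0.009628, -0.005698, 1.015326]]
_HPE = [[0.38971, 0.68898, -0.07868],
        [-0.22981, 1.18340, 0.04641],
        [0.0, 0.0, 1.0]]


def _matvec(m, v):
    return [sum(m[i][j] * v[j] for j in range(3)) for i in range(3)]


def oracle_ciecam02(xyz, xyzw, la=100.0, yb=20.0, d=1.0,
                    normalise_hpe=True):
    """Forward CIECAM02 returning (J, C, M, h, Jp, ap, bp)."""
    f, c, nc = 1.0, 0.69, 1.0  # average surround
    k = 1.0 / (5 * la + 1)
    fl = 0.2 * k**4 * 5 * la + 0.1 * (1 - k**4) ** 2 * (5 * la) ** (1 / 3)
    n = yb / xyzw[1]
    nbb = ncb = 0.725 * (1 / n) ** 0.2
    z = 1.48 + math.sqrt(n)
    if d is None:
        d = f * (1 - (1 / 3.6) * math.exp((-la - 42) / 92))

    hpe = [row[:] for row in _HPE]
    if normalise_hpe:
        for row in hpe:
            s = sum(row)
            row[:] = [x / s for x in row]

    rgb_w = _matvec(_CAT02, list(xyzw))
    dr = [xyzw[1] * d / rgb_w[i] + 1 - d for i in range(3)]
    rgb = _matvec(_CAT02, list(xyz))
    rgb_c = [rgb[i] * dr[i] for i in range(3)]
    rgb_wc = [rgb_w[i] * dr[i] for i in range(3)]
    rgb_p = _matvec(hpe, _matvec(_CAT02_INV, rgb_c))
    rgb_wp = _matvec(hpe, _matvec(_CAT02_INV, rgb_wc))

    def comp(x):
        t = (fl * abs(x) / 100.0) ** 0.42
        return math.copysign(400.0 * t / (t + 27.13), x) + 0.1

    ra, ga, ba = (comp(x) for x in rgb_p)
    raw, gaw, baw = (comp(x) for x in rgb_wp)
    a = ra - 12 * ga / 11 + ba / 11
    b = (ra + ga - 2 * ba) / 9
    h = math.degrees(math.atan2(b, a)) % 360
    et = 0.25 * (math.cos(math.radians(h) + 2) + 3.8)
    A = (2 * ra + ga + ba / 20 - 0.305) * nbb
    Aw = (2 * raw + gaw + baw / 20 - 0.305) * nbb
    J = 100 * (A / Aw) ** (c * z)
    denom = ra + ga + 21 * ba / 20
    t = (50000 / 13 * nc * ncb * et * math.hypot(a, b)) / denom if denom else 0
    t = max(t, 0.0)
    C = t**0.9 * math.sqrt(J / 100) * (1.64 - 0.29**n) ** 0.73
    M = C * fl**0.25
    jp = 1.7 * J / (1 + 0.007 * J)
    mp = math.log(1 + 0.0228 * M) / 0.0228
    return (J, C, M, h, jp, mp * math.cos(math.radians(h)),
            mp * math.sin(math.radians(h)))


# ---------------------------------------------------------------------------
# independent Ra and Rf
# ---------------------------------------------------------------------------

def _daylight_oracle(wl, T):
    # the daylight recipe is table data (S0/S1/S2 + locus polynomial);
    # reusing the package's reconstitution keeps the oracle focused on
    # the index machinery itself
    from spdcalc.reference_data import daylight_spd
    return daylight_spd(T, np.asarray(wl)).values


def oracle_reference(wl, cct, lo, hi):
    """Blended reference SPD with knees (lo, hi), Y-normalised mixing."""
    wl = np.asarray(wl, float)
    if cct <= lo:
        return oracle_planck(wl, cct)
    if cct >= hi:
        return _daylight_oracle(wl, min(cct, 25000.0))
    w = (hi - cct) / (hi - lo)
    p = oracle_planck(wl, cct)
    d = _daylight_oracle(wl, cct)
    return (w * p / oracle_xyz(wl, p)[1]
            + (1 - w) * d / oracle_xyz(wl, d)[1])


def oracle_ra(wl, spd):
    """General colour rendering index recomputed from scratch."""
    wl = np.asarray(wl, float)
    cct, duv = oracle_cct_brute(wl, spd)
    if abs(duv) > 0.05:
        return None
    ref = (oracle_planck(wl, cct) if cct < 5000.0
           else _daylight_oracle(wl, cct))
    tcs = get_table("cie13_3_8tcs", step_nm=wl[1] - wl[0])

    def render_uv_y(source):
        out = []
        k = 100.0 / oracle_xyz(wl, source)[1]
        for r in tcs.reflectances:
            X, Y, Z = oracle_xyz(wl, source * r)
            den = X + 15 * Y + 3 * Z
            out.append((4 * X / den, 6 * Y / den, k * Y))
        return out

    ut, vt = oracle_uv(wl, spd)
    ur, vr = oracle_uv(wl, ref)

    def cd(u, v):
        return (4 - u - 10 * v) / v, (1.708 * v + 0.404 - 1.481 * u) / v

    ct, dt = cd(ut, vt)
    cr, dr = cd(ur, vr)

    r_is = []
    for (uk, vk, yk_t), (ukr, vkr, yk_r) in zip(render_uv_y(spd),
                                                render_uv_y(ref)):
        ck, dk = cd(uk, vk)
        den = 16.518 + 1.481 * (cr / ct) * ck - (dr / dt) * dk
        uc = (10.872 + 0.404 * (cr / ct) * ck - 4 * (dr / dt) * dk) / den
        vc = 5.520 / den
        wt = 25 * yk_t ** (1 / 3) - 17
        wr_ = 25 * yk_r ** (1 / 3) - 17
        du = 13 * wt * (uc - ur) - 13 * wr_ * (ukr - ur)
        dv = 13 * wt * (vc - vr) - 13 * wr_ * (vkr - vr)
        dw = wt - wr_
        de = math.sqrt(du**2 + dv**2 + dw**2)
        r_is.append(round(100 - 4.6 * de))
    return sum(r_is) / len(r_is), r_is


def oracle_rf(wl, spd, lo=4000.0, hi=5000.0):
    """Colour fidelity index recomputed from scratch (cf = 6.73)."""
    wl = np.asarray(wl, float)
    cct, duv = oracle_cct_brute(wl, spd)
    if abs(duv) > 0.05:
        return None
    ref = oracle_reference(wl, cct, lo, hi)
    ces = get_table("tm30_99ces", step_nm=wl[1] - wl[0])

    def render(source):
        Xw, Yw, Zw = oracle_xyz(wl, source, "cie1964_10deg")
        k = 100.0 / Yw
        white = (k * Xw, 100.0, k * Zw)
        coords = []
        for r in ces.reflectances:
            xyz = [k * c for c in oracle_xyz(wl, source * r,
                                             "cie1964_10deg")]
            coords.append(oracle_ciecam02(xyz, white)[4:])
        return coords

    des = [
        math.dist(a, b) for a, b in zip(render(spd), render(ref))
    ]
    rf_prime = 100 - 6.73 * (sum(des) / len(des))
    return 10 * math.log(math.exp(rf_prime / 10) + 1)
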