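"""Standard tables, Planckian and daylight generators."""

import numpy as np
import pytest

from spdcalc.colorimetry import ChromaticitySystem, chromaticity, tristimulus
from spdcalc.reference_data import (ALPHA_CHANNELS, daylight_spd, get_table,
                                    planckian_spd, standard_grid)
from spdcalc.tables import load_packaged_table, read_table, write_table


def test_observer_tables_nonnegative_uniform():
    for name in ("cie1931_2deg", "cie1964_10deg"):
        obs = get_table(name)
        assert np.all(np.diff(obs.wavelengths) == 1.0)
        assert obs.wavelengths[0] == 380.0 and obs.wavelengths[-1] == 780.0
        for band in (obs.xbar, obs.ybar, obs.zbar):
            assert np.all(band >= 0.0)


def test_ybar_is_vlambda():
    """The 2° ybar column doubles as the photopic V(lambda) table."""
    obs = get_table("cie1931_2deg")
    vl = get_table("vlambda")
    np.testing.assert_array_equal(obs.ybar, vl[:, 1])
    # table maximum of 1.0000 at 555 nm
    assert vl[vl[:, 0] == 555.0, 1][0] == 1.0


def test_action_spectra_unit_peak_and_rhodopic():
    action = get_table("action_spectra")
    assert set(action.sensitivities) == set(ALPHA_CHANNELS)
    for ch in ALPHA_CHANNELS:
        vec = action[ch]
        assert np.all(vec >= 0.0)
        assert vec.max() == 1.0
    # melanopic peak lies in the 480-495 nm window
    mel_peak = action.wavelengths[np.argmax(action["mel"])]
    assert 480.0 <= mel_peak <= 495.0
    # rhodopic equals the scotopic table up to unit-peak normalisation
    vprime = get_table("vprime")
    np.testing.assert_allclose(action["rh"],
                               vprime[:, 1] / vprime[:, 1].max(), atol=1e-12)


def test_colour_sample_sets():
    tcs = get_table("cie13_3_8tcs")
    ces = get_table("tm30_99ces")
    assert len(tcs) == 8
    assert len(ces) == 99
    for sample_set in (tcs, ces):
        assert np.all(sample_set.reflectances >= 0.0)
        assert np.all(sample_set.reflectances <= 1.0)


def test_illuminant_library_names_and_span():
    lib = get_table("illuminants")
    expected = (["A", "C", "D50", "D65", "D75"]
                + [f"F{i}" for i in range(1, 13)]
                + [f"FL3.{i}" for i in range(1, 16)]
                + [f"HP{i}" for i in range(1, 6)]
                + [f"LED-B{i}" for i in range(1, 6)]
                + ["LED-BH1", "LED-RGB1", "LED-V1", "LED-V2"])
    for name in expected:
        s = lib[name]
        assert s.start_nm <= 380.0 and s.end_nm >= 780.0
    # case-insensitive resolution
    assert lib["d65"] == lib["D65"]
    with pytest.raises(KeyError, match="valid names"):
        lib["D55"]


def test_planckian_wien_peak():
    """Peak wavelength follows the Wien displacement law."""
    T = 5000.0
    grid = 380.0 + 0.1 * np.arange(4001)
    spd = planckian_spd(T, grid)
    lam_max = spd.wavelengths[np.argmax(spd.values)]
    assert lam_max == pytest.approx(2.8978e-3 / T * 1e9, abs=0.1)


def test_planckian_edge_ratio_closed_form():
    spd = planckian_spd(2856.0)
    c2 = 1.4388e-2
    expected = ((380e-9 / 780e-9) ** 5
                * np.expm1(c2 / (380e-9 * 2856.0))
                / np.expm1(c2 / (780e-9 * 2856.0)))
    assert spd.value_at(780.0) / spd.value_at(380.0) == pytest.approx(
        expected, rel=1e-12)


def test_planckian_rejects_nonpositive_temperature():
    with pytest.raises(ValueError):
        planckian_spd(0.0)
    with pytest.raises(ValueError):
        planckian_spd(-100.0)


def test_planckian_locus_monotone_uv():
    temps = np.linspace(2000.0, 10000.0, 17)
    uv = []
    for T in temps:
        pt = chromaticity(tristimulus(planckian_spd(T)),
                          ChromaticitySystem.UV_1960)
        uv.append((pt.a, pt.b))
    uv = np.array(uv)
    assert np.all(np.diff(uv[:, 0]) < 0)  # u strictly decreasing in T
    assert np.all(np.diff(uv[:, 1]) < 0)  # v strictly decreasing in T


@pytest.mark.parametrize("T", [4100.0, 5003.0, 6504.0, 11000.0, 24000.0])
def test_daylight_chromaticity_closes_on_locus(T):
    """The reconstituted daylight lands on (xD, yD) of the locus polynomial,
    with yD = -3.000 xD^2 + 2.870 xD - 0.275 by construction."""
    from spdcalc.reference_data import _daylight_locus_x
    xd = _daylight_locus_x(T)
    yd = -3.000 * xd**2 + 2.870 * xd - 0.275
    pt = chromaticity(tristimulus(daylight_spd(T)),
                      ChromaticitySystem.XY_1931)
    assert pt.a == pytest.approx(xd, abs=5e-4)
    assert pt.b == pytest.approx(yd, abs=5e-4)


def test_daylight_matches_vendored_d65(d65):
    spd = daylight_spd(6500.0 * 1.4388 / 1.4380)
    for s in (spd, d65):
        assert s.step_nm == 1.0
    a = chromaticity(tristimulus(spd), ChromaticitySystem.XY_1931)
    b = chromaticity(tristimulus(d65), ChromaticitySystem.XY_1931)
    assert a.a == pytest.approx(b.a, abs=1e-4)
    assert a.b == pytest.approx(b.b, abs=1e-4)


def test_daylight_domain_enforced():
    with pytest.raises(ValueError):
        daylight_spd(3999.0)
    with pytest.raises(ValueError):
        daylight_spd(25001.0)


def test_daylight_continuity():
    a = daylight_spd(5000.0)
    b = daylight_spd(5003.0)
    step = np.abs(b.values - a.values) / a.values.max()
    assert step.max() < 0.01


def test_get_table_unknown_name_lists_valid():
    with pytest.raises(KeyError, match="cie1931_2deg"):
        get_table("nonexistent")


def test_vendored_tables_roundtrip_byte_identical():
    from importlib import resources
    for filename in ("cmf_cie1931_2deg_5nm.csv", "cmf_cie1964_10deg_10nm.csv",
                     "vprime_scotopic_5nm.csv", "daylight_components_10nm.csv",
                     "illuminant_c_10nm.csv"):
        text = (resources.files("spdcalc") / "data" / filename).read_text()
        comments, names, data = read_table(text)
        # regenerate with the same cell formatting used in the files
        ncols = data.shape[1]
        fmts = {
            "cmf_cie1931_2deg_5nm.csv": ["{:.0f}"] + ["{:.6f}"] * 3,
            "cmf_cie1964_10deg_10nm.csv": ["{:.0f}"] + ["{:.6f}"] * 3,
            "vprime_scotopic_5nm.csv": ["{:.0f}", "{:.6f}"],
            "daylight_components_10nm.csv": ["{:.0f}"] + ["{:.2f}"] * 3,
            "illuminant_c_10nm.csv": ["{:.0f}", "{:.2f}"],
        }[filename]
        lines = comments + [",".join(names)]
        for row in data:
            lines.append(",".join(f.format(v) for f, v in zip(fmts, row)))
        assert "\n".join(lines) + "\n" == text


def test_planckian_scale_invariance_of_chromaticity():
    spd = planckian_spd(4000.0)
    doubled = spd.scaled(2.0)
    a = chromaticity(tristimulus(spd), ChromaticitySystem.XY_1931)
    b = chromaticity(tristimulus(doubled), ChromaticitySystem.XY_1931)
    assert (a.a, a.b) == (b.a, b.b)
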