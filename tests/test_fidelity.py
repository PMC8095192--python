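"""Colour rendering (Ra), colour fidelity (Rf) and TM-30 quantities."""

import numpy as np
import pytest

from oracles import oracle_ra, oracle_rf
from spdcalc.fidelity import (colour_fidelity_rf, colour_rendering_ra,
                              cvg_export, fidelity_report,
                              reference_illuminant, tm30_quantities)
from spdcalc.reference_data import get_table, planckian_spd
from spdcalc.spectra_io import parse_spectrum_csv, resample
from spdcalc.synthetic import SyntheticSpec, generate


# -- reference illuminant blending -----------------------------------------

def test_reference_blend_weights():
    assert reference_illuminant(4500.0, "cie224").weight_planckian == 0.5
    assert reference_illuminant(3000.0, "cie224").weight_planckian == 1.0
    assert reference_illuminant(3000.0, "cie224").descriptor == "planckian"
    assert reference_illuminant(5500.0, "tm30").weight_planckian == 0.0
    assert reference_illuminant(5500.0, "tm30").descriptor == "daylight"
    assert reference_illuminant(5000.0, "tm30").weight_planckian == 0.5
    # hard switch for the legacy scheme
    assert reference_illuminant(4999.0, "cie13_3").descriptor == "planckian"
    assert reference_illuminant(5000.0, "cie13_3").descriptor == "daylight"


def test_reference_blend_linear_in_cct():
    w = [reference_illuminant(c, "cie224").weight_planckian
         for c in (4000.0, 4250.0, 4500.0, 4750.0, 5000.0)]
    np.testing.assert_allclose(w, [1.0, 0.75, 0.5, 0.25, 0.0], atol=1e-12)


# -- self-reference identities ----------------------------------------------

@pytest.mark.parametrize("T", [2700.0, 3000.0, 3500.0])
def test_self_reference_planckian(T):
    spd = resample(planckian_spd(T), 1.0)
    ra, r_i = colour_rendering_ra(spd)
    assert ra == 100.0
    assert all(r == 100 for r in r_i)
    rf, rf_i, _ = colour_fidelity_rf(spd)
    assert rf == pytest.approx(100.0, abs=0.5)
    tm30 = tm30_quantities(spd)
    assert tm30.rg == pytest.approx(100.0, abs=0.1)
    assert tm30.rcs_h1 == pytest.approx(0.0, abs=0.1)


def test_self_reference_daylight():
    from spdcalc.reference_data import daylight_spd
    spd = daylight_spd(6500.0)
    ra, _ = colour_rendering_ra(spd)
    rf, _, _ = colour_fidelity_rf(spd)
    assert ra >= 99.0  # reference regeneration at the recovered CCT
    assert rf == pytest.approx(100.0, abs=0.5)


# -- oracle cross-checks ----------------------------------------------------

def test_ra_matches_independent_oracle(sample_csv_text):
    batch = parse_spectrum_csv(sample_csv_text)
    for s in batch:
        s1 = resample(s, 1.0)
        mine, _ = colour_rendering_ra(s1)
        theirs, _ = oracle_ra(s1.wavelengths, s1.values)
        assert mine == pytest.approx(theirs, abs=1.0)


def test_rf_matches_independent_oracle(sample_csv_text):
    batch = parse_spectrum_csv(sample_csv_text)
    for s in batch:
        s1 = resample(s, 1.0)
        mine, _, _ = colour_fidelity_rf(s1)
        theirs = oracle_rf(s1.wavelengths, s1.values)
        assert mine == pytest.approx(theirs, abs=0.1)


# -- structural and monotonicity properties ---------------------------------

def test_rf_decreases_with_notch_depth():
    last = 101.0
    for depth in (0.0, 0.3, 0.6, 0.9):
        spd = generate(SyntheticSpec("notch", {"T": 3000.0, "depth": depth,
                                               "centre": 575.0,
                                               "fwhm": 50.0}))
        rf, _, _ = colour_fidelity_rf(spd)
        assert rf < last
        last = rf


def test_rf_subindex_count_and_positive(sample_csv_text):
    s = parse_spectrum_csv(sample_csv_text)[1]
    rf, rf_i, ref = colour_fidelity_rf(s)
    assert len(rf_i) == 99
    assert rf > 0.0
    assert ref.cct > 0


def test_tm30_bin_count(planck3000):
    tm30 = tm30_quantities(planck3000)
    assert tm30.cvg_test.shape == (16, 2)
    assert tm30.cvg_reference.shape == (16, 2)
    # reference polygon is normalised onto the unit circle
    np.testing.assert_allclose(np.hypot(*tm30.cvg_reference.T), 1.0,
                               atol=1e-12)


def test_oversaturating_source_rg_above_100():
    """Narrowed RGB primaries amplify chroma: Rg > 100."""
    spd = generate(SyntheticSpec("rgb_led", {"weights": (1.1, 1.0, 0.9),
                                             "fwhm": 22.0}))
    tm30 = tm30_quantities(spd)
    assert tm30 is not None
    assert tm30.rg > 100.0


def test_na_propagation(mono530):
    assert colour_rendering_ra(mono530) == (None, None)
    assert colour_fidelity_rf(mono530) == (None, None, None)
    assert tm30_quantities(mono530) is None
    rep = fidelity_report(mono530, include_tm30=True)
    assert not rep.valid and rep.tm30 is None


def test_schemes_agree_outside_blend_region():
    """CIE 224 and TM-30 Rf coincide where both use a pure reference."""
    for T in (3500.0, 6500.0):
        spd = resample(planckian_spd(T), 1.0) if T < 5000 else None
        if spd is None:
            from spdcalc.reference_data import daylight_spd
            spd = daylight_spd(T)
        rf_cie, _, _ = colour_fidelity_rf(spd, "cie224")
        rf_tm, _, _ = colour_fidelity_rf(spd, "tm30")
        assert rf_cie == pytest.approx(rf_tm, abs=1e-9)


def test_blend_region_differs():
    f2 = get_table("illuminants")["F2"]  # CCT near 4570 K
    rf_cie, _, _ = colour_fidelity_rf(f2, "cie224")
    rf_tm, _, _ = colour_fidelity_rf(f2, "tm30")
    assert rf_cie != rf_tm


# -- CVG export --------------------------------------------------------------

def test_cvg_export_files(tmp_path, planck3000, mono530):
    tm30 = tm30_quantities(planck3000)
    path = tmp_path / "cvg.png"
    assert cvg_export(tm30, path) is True
    assert path.exists() and path.stat().st_size > 0
    with pytest.warns(UserWarning, match="N/A"):
        assert cvg_export(tm30_quantities(mono530),
                          tmp_path / "none.png") is False
    assert not (tmp_path / "none.png").exists()
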