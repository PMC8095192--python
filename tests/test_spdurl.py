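"""spdurl codec: golden string, round trips, quantisation bounds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spdcalc import spdurl
from spdcalc.reference_data import planckian_spd
from spdcalc.spectrum import Mode, Spectrum

GOLDEN = ("spd1,380,10,wi,4,uJuIuI4m68488W_h-38t7c6S6J5A3i4M4G4G3N1u0Hx-w0"
          "v0uwuFtmr-qsp2ohncrBvsxz2j")


def test_golden_decode_header_fields():
    rec = spdurl.decode(GOLDEN)
    assert rec.start_nm == 380.0
    assert rec.step_nm == 10.0
    assert rec.unit_code == "wi"
    assert rec.exponent == 4
    assert len(rec.mantissas) == 36


def test_golden_reencode_byte_identical():
    rec = spdurl.decode(GOLDEN)
    assert spdurl.encode(rec) == GOLDEN
    assert len(spdurl.encode(rec)) <= 90


def test_golden_value_level_roundtrip():
    """decode -> values -> encode reproduces the exact string."""
    rec = spdurl.decode(GOLDEN)
    spec = spdurl.record_to_spectrum(rec)
    assert spdurl.encode(spec, unit=rec.unit_code) == GOLDEN


def test_mantissa_field_two_chars_per_band():
    vals = np.linspace(0.1, 1.0, 36)
    s = Spectrum.from_nm(380.0, 10.0, vals)
    mant = spdurl.encode(s, unit="wi").split(",")[5]
    assert len(mant) == 72


def test_all_zero_spectrum():
    s = Spectrum.from_nm(380.0, 10.0, np.zeros(10))
    text = spdurl.encode(s, unit="wi")
    rec = spdurl.decode(text)
    assert len(text.split(",")[5]) == 20
    assert all(m == 0 for m in rec.mantissas)
    np.testing.assert_array_equal(spdurl.record_values(rec), 0.0)


def test_quantisation_error_bound(rng):
    """<= 0.2 % relative error for bands above 1 % of the maximum."""
    for _ in range(20):
        vals = rng.uniform(1e-3, 1.0, 101) * rng.uniform(1e-6, 1e6)
        s = Spectrum.from_nm(380.0, 4.0, vals)
        rec = spdurl.decode(spdurl.encode(s, unit="wi"))
        back = spdurl.record_values(rec)
        mask = vals >= 0.01 * vals.max()
        rel = np.abs(back[mask] - vals[mask]) / vals[mask]
        assert rel.max() <= 2e-3


def test_scale_covariance(rng):
    vals = rng.uniform(0.0, 1.0, 50)
    s = Spectrum.from_nm(400.0, 2.0, vals)
    rec1 = spdurl.decode(spdurl.encode(s, unit="wi"))
    # an exact power of the exponent base shifts only the exponent
    k = spdurl.BASE ** 8
    rec2 = spdurl.decode(spdurl.encode(s.scaled(k), unit="wi"))
    assert rec2.exponent == rec1.exponent + 8
    assert max(abs(a - b) for a, b in zip(rec1.mantissas,
                                          rec2.mantissas)) <= 1


def test_negative_values_rejected_or_clamped():
    s = Spectrum.from_nm(380.0, 10.0, np.array([1.0, -0.5, 2.0]))
    with pytest.raises(spdurl.SpdUrlError, match="E_SPD_NEGATIVE"):
        spdurl.encode(s, unit="wi")
    rec = spdurl.decode(spdurl.encode(s, unit="wi", clamp_negative=True))
    assert spdurl.record_values(rec)[1] == 0.0


def test_decode_error_codes():
    with pytest.raises(spdurl.SpdUrlError, match="E_SPD_VERSION"):
        spdurl.decode("spd2,380,10,wi,4,AAAA")
    with pytest.raises(spdurl.SpdUrlError, match="E_SPD_LENGTH"):
        spdurl.decode(GOLDEN[:-1])  # odd mantissa length
    with pytest.raises(spdurl.SpdUrlError, match="E_SPD_CHAR"):
        spdurl.decode("spd1,380,10,wi,4,AA=!")
    with pytest.raises(spdurl.SpdUrlError, match="E_SPD_UNIT"):
        spdurl.decode("spd1,380,10,zzz,4,AAAA")


def test_metadata_roundtrip_percent_encoding():
    s = Spectrum.from_nm(380.0, 10.0, np.linspace(0.0, 1.0, 11))
    text = spdurl.encode(s, unit="wi", metadata={"name": "Measurement 1"})
    assert text.endswith(",nMeasurement%201")
    rec = spdurl.decode(text)
    assert rec.metadata == {"name": "Measurement 1"}


def test_share_url_prefix_and_reconstruction():
    rec = spdurl.decode(GOLDEN)
    url = spdurl.share_url(rec)
    assert url == "https://luox.app/u/" + GOLDEN
    # URL with metadata matches the documented form
    url2 = spdurl.share_url(rec, metadata={"name": "Measurement 1"})
    assert url2 == "https://luox.app/u/" + GOLDEN + ",nMeasurement%201"


def test_half_nm_spectrum_fits_in_budget():
    grid = 380.0 + 0.5 * np.arange(801)
    vals = planckian_spd(3000.0, np.arange(380.0, 781.0)).values
    fine = np.interp(grid, np.arange(380.0, 781.0), vals)
    s = Spectrum.from_nm(380.0, 0.5, fine, Mode.RADIANCE)
    text = spdurl.encode(s, unit="wr")
    assert len(text) <= 2048


def test_units_dictionary_complete():
    assert len(spdurl.UNITS) == 30
    assert spdurl.UNITS["wi"] == "W/m^2/nm"
    assert spdurl.UNITS["uwi"] == "uW/cm^2/nm"
    assert all(2 <= len(code) <= 3 for code in spdurl.UNITS)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    start=st.integers(300, 500),
    step=st.sampled_from([1, 2, 5, 10]),
    exponent=st.integers(-40, 40),
    mantissas=st.lists(st.integers(0, 4095), min_size=1, max_size=64),
)
def test_record_roundtrip_property(start, step, exponent, mantissas):
    rec = spdurl.SpdUrlRecord(float(start), float(step), "uwi", exponent,
                              tuple(mantissas))
    back = spdurl.decode(spdurl.encode(rec))
    assert back == rec
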