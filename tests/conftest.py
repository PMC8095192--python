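import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from spdcalc.reference_data import get_table, planckian_spd
from spdcalc.spectra_io import resample
from spdcalc.synthetic import SyntheticSpec, generate


@pytest.fixture(scope="session")
def sample_csv_text() -> str:
    from importlib import resources
    return (resources.files("spdcalc") / "data"
            / "sample_fseries_5nm.csv").read_text()


@pytest.fixture(scope="session")
def d65():
    return get_table("illuminants")["D65"]


@pytest.fixture(scope="session")
def planck3000():
    return resample(planckian_spd(3000.0), 1.0)


@pytest.fixture(scope="session")
def mono530():
    return generate(SyntheticSpec("monochromatic", {"peak": 530,
                                                    "power": 1.0}))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
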