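import warnings

import numpy as np
import pytest

import saosfit as sf

# small test sweeps legitimately span < 3 decades; silence the data-quality
# advisory so it does not drown test output
warnings.simplefilter("ignore", sf.NarrowFrequencyRangeWarning)


@pytest.fixture(autouse=True)
def _quiet_narrow_range():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sf.NarrowFrequencyRangeWarning)
        yield


@pytest.fixture
def burgers():
    return sf.get_model("burgers")


@pytest.fixture
def toy_burgers_params():
    """Algebraically convenient Burgers parameters with simple exact K."""
    return {"E1": 2.0, "E2": 3.0, "eta1": 5.0, "eta2": 7.0}


@pytest.fixture
def alginate_params():
    """Burgers parameters of the scale identified for a 3% (w/v) alginate
    solution: stiff moduli (~500-700 Pa) and ~10 Pa.s viscosities, giving
    relaxation times near 0.016 s."""
    return {"E1": 697.69, "E2": 511.27, "eta1": 11.07, "eta2": 8.38}


@pytest.fixture
def simple_sweep():
    return sf.FrequencySweep(
        omega=np.array([0.1, 1.0, 10.0]),
        g_prime=np.array([1.0, 2.0, 3.0]),
        g_double_prime=np.array([4.0, 5.0, 6.0]),
    )


def write_csv(path, text):
    path.write_text(text)
    return path
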