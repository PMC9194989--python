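import pytest

from tldose.coefficients import load_coefficients
from tldose.effective_dose import load_protocols, load_reference_organ_doses
from tldose.spectrum import generate_spectrum


@pytest.fixture(scope="session")
def coeffs():
    return load_coefficients()


@pytest.fixture(scope="session")
def spectrum_80kvp(coeffs):
    return generate_spectrum(80.0, [("Al", 5.0)], coeffs=coeffs)


@pytest.fixture(scope="session")
def reference_doses():
    return load_reference_organ_doses()


@pytest.fixture(scope="session")
def protocols():
    return load_protocols()
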