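import pytest

from teer_cea import default_parameters
from teer_cea.parameters import load_parameters, to_document


@pytest.fixture(scope="session")
def params():
    """Shipped calibrated base-case parameter set."""
    return default_parameters()


@pytest.fixture(scope="session")
def params_no_hcc(params):
    """Base case with half-cycle correction disabled (microsim convention)."""
    doc = to_document(params)
    doc["model"]["half_cycle_correction"] = False
    return load_parameters(doc)


@pytest.fixture()
def document(params):
    """Mutable copy of the base-case configuration document."""
    return to_document(params)


#: lifetime outcomes reported for the base case (used as calibration targets)
REPORTED = {
    "life_years.mitraclip": 3.72,
    "life_years.omt": 2.90,
    "hospitalizations.mitraclip": 1.16,
    "hospitalizations.omt": 1.51,
    "qaly.mitraclip": 2.32,
    "qaly.omt": 1.80,
    "lifetime_cost.mitraclip": 423_817.0,
    "lifetime_cost.omt": 28_369.0,
    "icer": 754_410.0,
}
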