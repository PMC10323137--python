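import numpy as np
import pytest
from hypothesis import settings

from vancomipd import PKParameters, RegimenSpec

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def case_params() -> PKParameters:
    """Population one-compartment parameters of the packaged case patient."""
    return PKParameters.one_compartment_from_ke(ke=0.104, Vd=55.9)


@pytest.fixture
def case_regimen() -> RegimenSpec:
    """1250 mg q8h infused over 90 min."""
    return RegimenSpec(dose=1250.0, interval=8.0, infusion_duration=1.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1729)
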