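import numpy as np
import pytest

from smcpk import (
    CovariateLaw,
    CovariateVector,
    DosingRegimen,
    PopPKModel,
    default_zoo,
    separated_zoo,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def simple_model():
    """A model with a clean crcl-only clearance law for closed-form checks."""
    law = CovariateLaw(cl_typical=5.0, v_typical=50.0, cl_crcl_exp=0.75, cl_weight_exp=0.0)
    return PopPKModel("simple", law, omega_cl=0.25, omega_v=0.2, sigma_prop=0.1, sigma_add=1.0)


@pytest.fixture
def reference_patient():
    return CovariateVector(age=50.0, height=170.0, weight=70.0, crcl=100.0)


@pytest.fixture
def regimen():
    return DosingRegimen(dose=1000.0, infusion_duration=1.0, interval=12.0, n_doses=4)


@pytest.fixture(scope="session")
def zoo6():
    return default_zoo()


@pytest.fixture(scope="session")
def zoo3():
    return separated_zoo(3)
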