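import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nafamopk as nk
from nafamopk.estimation import FitSettings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def patient_model():
    return nk.load_model("patient")


@pytest.fixture(scope="session")
def ecmo_model():
    return nk.load_model("ecmo")


@pytest.fixture(scope="session")
def synthetic_study(patient_model, ecmo_model):
    """One default-design virtual trial shared across tests (read-only)."""
    design = nk.StudyDesign()
    return nk.generate_study(design, patient_model, ecmo_model, rng_seed=11)


@pytest.fixture(scope="session")
def fast_settings():
    return FitSettings.fast()


@pytest.fixture
def const_infusion():
    def make(rate=30.0, start=0.0, end=np.inf):
        return [nk.DoseEvent(start, end, rate)]

    return make
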