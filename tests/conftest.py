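import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import smrkit as sk
from smrkit.pipeline import TRUE_MODEL_VARIABLES, StudyConfig, run_study

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def casemix():
    return sk.default_casemix()


@pytest.fixture(scope="session")
def true_model():
    return sk.default_true_model()


@pytest.fixture(scope="session")
def clean_registries(casemix, true_model):
    """Paired registries for 20 hospitals with no degradation at all."""
    hospitals = sk.generate_hospitals(20, 11, "clean")
    truth = sk.generate_admin_registry(hospitals, casemix, true_model, 12)
    clinical = sk.degrade_to_clinical_registry(truth, hospitals, 13)
    return hospitals, truth, clinical


@pytest.fixture(scope="session")
def fast_study():
    """One paper-like study with the reference variable set (no selection)."""
    return run_study(StudyConfig(seed=5, variables=TRUE_MODEL_VARIABLES))


def make_registry(n, seed=0, casemix=None, model=None, facility_id="H000"):
    casemix = casemix or sk.default_casemix()
    model = model or sk.default_true_model()
    return sk.simulate_patients(n, casemix, model, seed, facility_id=facility_id)
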