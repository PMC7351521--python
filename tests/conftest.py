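import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from busulfan_mipd import (
    PatientCovariates,
    StrategyModels,
    build_regimen,
    default_model,
    first_generation_model,
)


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def models():
    return StrategyModels(
        truth=default_model(),
        second_gen=default_model(),
        first_gen=first_generation_model(),
    )


@pytest.fixture
def child_cov():
    """A school-age malignant-disease patient."""
    return PatientCovariates(
        patient_id="child-1", age=5.9, weight=17.8, height=112.0, sex="male",
        disease_class="malignant", regimen_label="bu_flu",
    )


@pytest.fixture
def infant_cov():
    """A non-malignant infant (q24 dosing territory)."""
    return PatientCovariates(
        patient_id="infant-1", age=1.4, weight=10.2, height=78.0, sex="female",
        disease_class="nonmalignant", regimen_label="bu_flu",
    )


@pytest.fixture
def q6_regimen():
    """16 equal doses of 10 mg q6h over 4 days, 2-h infusions."""
    return build_regimen(10.0, 6, 4)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
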