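import numpy as np
import pytest

from abstaindx import Subject, study_confusion


@pytest.fixture(scope="session")
def table3():
    """The published trial confusion matrix (grand total 425)."""
    return study_confusion()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_subject(true_class="comorbid_only", age_months=36, z=0.0):
    """Minimal valid subject for panel tests."""
    return Subject(
        id="T00000", age_months=age_months, sex="female",
        race_ethnicity=frozenset({"unknown"}), income_band="50k_75k",
        education_band="bachelor", true_class=true_class, z=z,
        sc_severity=2 if true_class == "ASD" else None,
        rrb_severity=2 if true_class == "ASD" else None,
        comorbidities=(frozenset({"language_disorder"})
                       if true_class == "comorbid_only" else frozenset()),
        responses=np.zeros(64),
    )


@pytest.fixture()
def subject_factory():
    return make_subject
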