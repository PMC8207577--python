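import numpy as np
import pytest

from edies import builtin_reference, builtin_score_table
from edies.cohort_io import PatientRecord


@pytest.fixture(scope="session")
def table():
    return builtin_score_table()


@pytest.fixture(scope="session")
def reference():
    return builtin_reference(warn_non_monotone=False)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_record(**overrides) -> PatientRecord:
    """A fully populated record scoring 3 under the built-in table
    (male + disease, everything else at a zero bin)."""
    base = dict(
        id="r1", age=30, sex="male", cause="disease", avpu="A",
        sbp=120.0, dbp=80.0, hr=80.0, rr=16.0, bt=36.6, spo2=99.0,
        arrival_arrest=False, transferred_out=False,
        ed_result="discharged", hospital_result="not_admitted",
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture
def record_factory():
    return make_record
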