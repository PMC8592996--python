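import warnings

import numpy as np
import pytest

import spineload as sl
from spineload.synth import load_tasks


@pytest.fixture(scope="session")
def male_subject() -> sl.SubjectProfile:
    # group-mean male anthropometry
    return sl.SubjectProfile("male", 1.769, 77.3, 33.0)


@pytest.fixture(scope="session")
def female_subject() -> sl.SubjectProfile:
    return sl.SubjectProfile("female", 1.685, 56.4, 31.9)


@pytest.fixture(scope="session")
def male_params(male_subject):
    return sl.make_parameter_set("male_base", male_subject)


@pytest.fixture(scope="session")
def male_chain(male_subject, male_params):
    return sl.build_chain(male_subject, male_params)


@pytest.fixture(scope="session")
def tasks():
    return load_tasks()


@pytest.fixture(scope="session")
def rhythm():
    from spineload.synth import load_rhythm

    return load_rhythm()


@pytest.fixture(autouse=True)
def _no_bmi_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
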