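import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from denshare import load_paper_tables
from denshare.inference import fit_mixed, fit_single_sex

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tables():
    """The study's eight replicates, keyed by table label '1a'..'4b'."""
    return load_paper_tables()


@pytest.fixture(scope="session")
def ff(tables):
    return [tables["3a"], tables["3b"]]


@pytest.fixture(scope="session")
def mm(tables):
    return [tables["4a"], tables["4b"]]


@pytest.fixture(scope="session")
def fm(tables):
    return [tables["1a"], tables["1b"]]


@pytest.fixture(scope="session")
def pl(tables):
    return [tables["2a"], tables["2b"]]


@pytest.fixture(scope="session")
def ff_fit(ff):
    return fit_single_sex(ff)


@pytest.fixture(scope="session")
def mm_fit(mm):
    return fit_single_sex(mm)


@pytest.fixture(scope="session")
def fm_fit(fm):
    return fit_mixed(fm)
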