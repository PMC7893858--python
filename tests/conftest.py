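import pytest
from hypothesis import settings

from codonscope import normalize, standard_code, toy_table, validate_cds

settings.register_profile(
    "codonscope", derandomize=True, deadline=None, database=None
)
settings.load_profile("codonscope")


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def table():
    return toy_table()


@pytest.fixture(scope="session")
def freqs(table, code):
    return normalize(table, code)


@pytest.fixture
def cds():
    def make(seq, id="cds"):
        return validate_cds(seq, id)

    return make
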