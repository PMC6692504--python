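import pytest

from matsys.synthetic_data import rdna_landmark, toy_queries


@pytest.fixture(scope="session")
def queries():
    return toy_queries()


@pytest.fixture(scope="session")
def rdna():
    return rdna_landmark()
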