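import pytest

from pafkit import load_fixture


@pytest.fixture(scope="session")
def table1():
    """Two-stratum binary-exposure population with constant stratum RR 1.5."""
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table1_em():
    """Same population with effect modification (stratum RRs 1.5 and 3)."""
    return load_fixture("table1_em")
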