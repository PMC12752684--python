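import pytest

from fibrilshift.reference_data import (
    ialpha_reference,
    ibeta_reference,
    poplar_reference,
)


@pytest.fixture(scope="session")
def poplar():
    return poplar_reference()


@pytest.fixture(scope="session")
def majors(poplar):
    return poplar.major_sites()


@pytest.fixture(scope="session")
def ibeta():
    return ibeta_reference()


@pytest.fixture(scope="session")
def ialpha():
    return ialpha_reference()
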