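import pytest

from dpdsurf import load_forcefield


@pytest.fixture(scope="session")
def ff():
    return load_forcefield("revised")


@pytest.fixture(scope="session")
def ff_original():
    return load_forcefield("original")
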