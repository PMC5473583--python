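import pytest

from mufatigue import PoolParameters, build_pool


@pytest.fixture(scope="session")
def params():
    return PoolParameters()


@pytest.fixture(scope="session")
def pool(params):
    return build_pool(params)
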