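import numpy as np
import pytest

from pkashift import tables


@pytest.fixture(scope="session")
def folded_table():
    return tables.folded_pka_table()


@pytest.fixture(scope="session")
def unfolded_table():
    return tables.unfolded_pka_table()


@pytest.fixture(scope="session")
def published_ddg():
    return tables.ddg_table()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
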