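import numpy as np
import pytest

from cultivopt.dataset import load_table1


@pytest.fixture(scope="session")
def table1():
    """The packaged 66-treatment light × sucrose dataset."""
    return load_table1()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
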