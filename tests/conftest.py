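import numpy as np
import pytest

from trunclindley import load_dataset


@pytest.fixture(scope="session")
def temperatures():
    return load_dataset("temperatures")


@pytest.fixture(scope="session")
def carbon_fibers():
    return load_dataset("carbon_fibers")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
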