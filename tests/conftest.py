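import numpy as np
import pytest

from deltabind import build_toy_dimer


@pytest.fixture(scope="session")
def wt_system():
    return build_toy_dimer(5, 4, "WT", 7)


@pytest.fixture(scope="session")
def mut_system():
    return build_toy_dimer(5, 4, "MUT", 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
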