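import numpy as np
import pytest

from tsmr import make_erysipelotrichia_fixture


@pytest.fixture(scope="session")
def worked_example():
    """The five published per-SNP Wald ratios (class Erysipelotrichia vs NB)."""
    return make_erysipelotrichia_fixture()


@pytest.fixture(scope="session")
def worked_example_arrays(worked_example):
    b = np.array([r.b for r in worked_example])
    se = np.array([r.se for r in worked_example])
    return b, se
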