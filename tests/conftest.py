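import numpy as np
import pytest

import sempower as sp


@pytest.fixture(scope="session")
def patterns():
    """Fitted patterns of the three candidate models (variance-standardized)."""
    return sp.candidate_patterns()


@pytest.fixture(scope="session")
def tripartite_pop():
    """The headline population model: a=0.7, all factor correlations 0.3."""
    return sp.build_tripartite(0.7, 0.3)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240501)
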