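import numpy as np
import pytest

import gamedx as g
from gamedx.cohort import PERFECT_TRAITS


@pytest.fixture(scope="session")
def default_config():
    """Session config at the 50 Hz simulation rate used throughout tests."""
    return g.build_default_session_config({"sampling_rate": 50.0})


@pytest.fixture(scope="session")
def study():
    """One full simulated study (cohort, sessions, preprocessed features)."""
    cohort, records, matrix, scfg = g.simulate_study(seed=1)
    return {"cohort": cohort, "records": records, "matrix": matrix,
            "config": scfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def perfect_traits():
    return PERFECT_TRAITS
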