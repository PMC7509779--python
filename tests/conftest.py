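import numpy as np
import pandas as pd
import pytest

from flowparse import CohortSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A 5-participant end-to-end dataset shared by the pipeline tests."""
    spec = CohortSpec(n_participants=5, seed=20240)
    return simulate_dataset(spec)


@pytest.fixture
def psych_fixture_40():
    """Fixed 40-trial binary response table for brute-force fit checks."""
    gen = np.random.default_rng(77)
    v = np.round(gen.uniform(-0.8, 0.8, 40), 3)
    from scipy.stats import norm
    z = (gen.random(40) < norm.cdf((v - 0.1) / 0.3)).astype(int)
    return pd.DataFrame({"velocity_cm_s": v, "response_right": z})
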