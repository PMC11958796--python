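import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from comland import data_model as dm
from comland.synthetic_data import fixture_config, simulate


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic experiment shared across tests (40 parents)."""
    return simulate(fixture_config("small", seed=1))


@pytest.fixture
def toy_counts():
    """3 samples x 3 ASVs with easy hand-checkable totals."""
    return dm.CountTable(pd.DataFrame(
        [[100, 40, 60], [30, 29, 20], [20, 30, 20]],
        index=["s1", "s2", "s3"], columns=["a1", "a2", "a3"]))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_composition_table(rng, n, p, alpha=0.8):
    comp = rng.dirichlet(np.full(p, alpha), size=n)
    return pd.DataFrame(comp, index=[f"s{i}" for i in range(n)],
                        columns=[f"a{j}" for j in range(p)])
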