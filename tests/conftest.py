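import numpy as np
import pandas as pd
import pytest

from invanet.synthetic import SyntheticConfig, simulate_counts


@pytest.fixture(scope="session")
def small_config():
    """Down-scaled study design used where only structure matters."""
    return SyntheticConfig(
        n_sites={"invaded": 3, "native": 2},
        n_reps_per_site=3,
        n_taxa=60,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_counts(small_config)


@pytest.fixture()
def toy_counts():
    """Four samples x three taxa with simple round numbers."""
    return pd.DataFrame(
        [[2, 2, 0], [1, 0, 3], [5, 5, 10], [1, 1, 2]],
        index=["s1", "s2", "s3", "s4"],
        columns=["t1", "t2", "t3"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
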