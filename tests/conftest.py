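import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy.spatial.distance import squareform

from genelang import (
    DistanceMatrix,
    PopulationPanel,
    SyntheticConfig,
    generate_dataset,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_921)


def make_random_dm(rng, n, ids=None, kind="generic"):
    """A random labelled distance matrix (positive off-diagonals)."""
    ids = ids or [f"P{i:02d}" for i in range(n)]
    vec = rng.random(n * (n - 1) // 2) + 0.05
    return DistanceMatrix(squareform(vec), ids, kind=kind)


@pytest.fixture
def small_panel():
    table = pd.DataFrame(
        {
            "latitude": [35.0, 40.0, 28.0, 52.0, 47.0, 38.5],
            "longitude": [51.0, 45.0, 77.0, 20.0, 8.0, 23.7],
            "group": ["Indo-Iranian"] * 3 + ["European"] * 3,
        },
        index=["teh", "yer", "del", "war", "ber", "ath"],
    )
    return PopulationPanel(table)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_pop_group1=5,
        n_pop_group2=7,
        n_haplogroups_y=8,
        n_haplogroups_mt=8,
        n_lexical_traits=80,
        n_phoneme_traits=80,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config, seed=11)


@pytest.fixture(scope="session")
def default_dataset():
    """One full-size panel under the default planted-effect structure."""
    return generate_dataset(SyntheticConfig(), seed=5)
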