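import numpy as np
import pandas as pd
import pytest

from rhizotrace import synthio


@pytest.fixture
def small_community():
    """6 samples x 5 taxa with two clearly different groups."""
    counts = np.array([
        [30, 20, 5, 0, 1],
        [28, 22, 4, 1, 0],
        [31, 19, 6, 0, 2],
        [2, 1, 25, 30, 10],
        [1, 2, 28, 27, 12],
        [3, 0, 24, 31, 9],
    ])
    table = pd.DataFrame(
        counts,
        index=[f"S{i}" for i in range(6)],
        columns=list("ABCDE"),
    )
    groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=table.index)
    return table, groups


@pytest.fixture
def default_config():
    return synthio.SimulationConfig(seed=7)


def random_count_table(rng, n_samples=6, n_taxa=8, depth=200):
    counts = rng.multinomial(depth, rng.dirichlet(np.ones(n_taxa)),
                             size=n_samples)
    return pd.DataFrame(
        counts, index=[f"S{i}" for i in range(n_samples)],
        columns=[f"t{j}" for j in range(n_taxa)],
    )
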