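import numpy as np
import pandas as pd
import pytest

from micreco.data import OtuTable
from micreco.synthetic import simulate_study


@pytest.fixture(scope="session")
def study_bundle():
    """One small six-group study bundle shared by read-only tests."""
    return simulate_study(seed=7, n_taxa=400, samples_per_group=4, depth=10_000)


@pytest.fixture()
def toy_table():
    counts = pd.DataFrame(
        [[5, 3, 1, 1, 2], [4, 4, 0, 2, 0], [0, 0, 7, 3, 0], [1, 1, 1, 1, 1]],
        index=["s1", "s2", "s3", "s4"],
        columns=[f"otu{i}" for i in range(1, 6)],
    )
    meta = pd.DataFrame(
        {"group": ["a", "a", "b", "b"]}, index=["s1", "s2", "s3", "s4"]
    )
    return OtuTable(counts, meta)


def random_table(rng: np.random.Generator, n_samples: int, n_otus: int,
                 depth: int = 1000, n_groups: int = 2) -> OtuTable:
    """Helper: multinomial table with random positive pool."""
    pool = rng.dirichlet(np.ones(n_otus))
    counts = np.vstack([rng.multinomial(depth, pool) for _ in range(n_samples)])
    # guarantee positive totals
    counts[:, 0] += 1
    ids = [f"s{i}" for i in range(n_samples)]
    groups = [f"g{i % n_groups}" for i in range(n_samples)]
    return OtuTable(
        pd.DataFrame(counts, index=ids, columns=[f"otu{j}" for j in range(n_otus)]),
        pd.DataFrame({"group": groups}, index=ids),
    )
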