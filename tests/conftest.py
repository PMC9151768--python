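import numpy as np
import pandas as pd
import pytest

import editscape as es


@pytest.fixture(scope="session")
def genome():
    return es.build_synthetic_genome(seed=1)


@pytest.fixture(scope="session")
def truth(genome):
    return es.simulate_editing_truth(genome, n_sites=300, seed=2)


@pytest.fixture(scope="session")
def fans_samples(truth, genome):
    """Default FANS design pileups at moderate coverage."""
    return es.simulate_pileups(truth, genome, mean_coverage=50, seed=3, n_background=100)


@pytest.fixture(scope="session")
def two_group_matrix():
    """A directly constructed two-cell-type SiteMatrix: 200 shifted + 800 null sites."""
    rng = np.random.default_rng(0)
    n = 9
    donors = [f"D{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "cell_type": ["A"] * n + ["B"] * n,
            "donor": donors * 2,
            "age": list(rng.uniform(25, 90, n)) * 2,
            "PMI": list(rng.uniform(5, 40, n)) * 2,
        },
        index=[f"{d}_{c}" for c in "AB" for d in donors],
    )
    shift = np.hstack([np.full((200, n), 0.2), np.zeros((200, n))])
    lv = np.vstack(
        [
            np.clip(0.3 + shift + rng.normal(0, 0.05, (200, 2 * n)), 0, 1),
            np.clip(0.3 + rng.normal(0, 0.05, (800, 2 * n)), 0, 1),
        ]
    )
    levels = pd.DataFrame(lv, index=[f"s{i}" for i in range(1000)], columns=meta.index)
    ones = levels.notna().astype(int)
    return es.SiteMatrix(
        sites=pd.DataFrame(index=levels.index),
        levels=levels,
        coverage=ones,
        edited=ones,
        samples=meta,
    )
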