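import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sigrank import GeneratorConfig, generate_dataset, rank_genes

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_expr():
    """10-gene, 3-sample expression frame with strictly distinct values."""
    rng = np.random.default_rng(7)
    vals = rng.permutation(30).reshape(10, 3).astype(float)
    return pd.DataFrame(
        vals, index=[f"g{i}" for i in range(10)], columns=["s0", "s1", "s2"]
    )


@pytest.fixture(scope="session")
def small_ranks(small_expr):
    return rank_genes(small_expr)


@pytest.fixture(scope="session")
def planted_dataset():
    """Desk-scale synthetic cohort with a strong planted signature (delta=2)."""
    cfg = GeneratorConfig(
        n_genes=500, n_samples=120, n_up=20, n_down=20, delta=2.0, seed=11
    )
    return generate_dataset(cfg)


def assign_ranks(gene_ids, rank_map, n_universe, sample="s"):
    """Build a RankMatrix-like frame where chosen genes get chosen ranks.

    Remaining ranks are distributed over filler genes so each column is
    a permutation of 1..N.
    """
    from sigrank import RankMatrix

    taken = set(rank_map.values())
    free = [r for r in range(1, n_universe + 1) if r not in taken]
    ids = list(rank_map) + [f"filler{i}" for i in range(n_universe - len(rank_map))]
    ranks = list(rank_map.values()) + free
    df = pd.DataFrame({sample: ranks}, index=ids)
    return RankMatrix(ranks=df)
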