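import numpy as np
import pandas as pd
import pytest

from guildnet import AbundanceTable, CovarianceSpec, simulate_counts, to_relative


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng) -> AbundanceTable:
    """10 taxa x 12 samples of random counts, no planted structure."""
    counts = rng.integers(0, 500, size=(10, 12)).astype(float)
    ids = [f"t{i:02d}" for i in range(10)]
    samples = [f"s{i:02d}" for i in range(12)]
    return AbundanceTable(pd.DataFrame(counts, index=ids, columns=samples), kind="counts")


@pytest.fixture(scope="session")
def planted_blocks():
    """30-taxon table with four planted modules, n=500, no structural zeros."""
    spec = CovarianceSpec(n_taxa=30, module_sizes=[8, 8, 7, 7], within_r=0.8)
    table, truth = simulate_counts(spec, 500, depth=100_000, zero_inflation=0.0, seed=11)
    return spec, table, truth


@pytest.fixture
def zero_free_relative(rng) -> AbundanceTable:
    """Strictly positive relative table (SparCC oracle comparisons)."""
    raw = rng.lognormal(0.0, 1.0, size=(6, 15))
    rel = raw / raw.sum(axis=0, keepdims=True)
    ids = [f"t{i}" for i in range(6)]
    samples = [f"s{i}" for i in range(15)]
    return AbundanceTable(pd.DataFrame(rel, index=ids, columns=samples), kind="relative")


@pytest.fixture
def small_relative(small_counts) -> AbundanceTable:
    return to_relative(small_counts)
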