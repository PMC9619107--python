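import itertools

import numpy as np
import pandas as pd
import pytest

import dircorr as dc
from dircorr import PairedSeries, load_worked_example
from dircorr.ordinal import PairCounts


@pytest.fixture(scope="session")
def worked_example():
    """The bundled 20-person, 6-item dataset with score column X."""
    return load_worked_example()


@pytest.fixture(scope="session")
def pairs(worked_example):
    """PairedSeries for every item column against the score."""
    x = worked_example["X"].to_numpy()
    return {
        name: PairedSeries(worked_example[name].to_numpy(), x)
        for name in ("A1", "A2", "A3", "B1", "B2", "B3")
    }


@pytest.fixture(scope="session")
def study_items():
    """Pooled per-item table over a seeded 200-test synthetic collection."""
    tests = dc.generate_test_collection(dc.TestCollectionSpec(n_tests=200, seed=1))
    tables = [dc.item_analysis_table(t.responses) for t in tests]
    return pd.concat(tables, ignore_index=True)


def brute_pair_counts(g: np.ndarray, x: np.ndarray) -> PairCounts:
    """O(n²) enumeration of all unordered pairs — the counting oracle."""
    c = d = tg = tx = tb = 0
    for i, j in itertools.combinations(range(len(g)), 2):
        dg = g[i] - g[j]
        dx = x[i] - x[j]
        if dg == 0 and dx == 0:
            tb += 1
        elif dg == 0:
            tg += 1
        elif dx == 0:
            tx += 1
        elif dg * dx > 0:
            c += 1
        else:
            d += 1
    return PairCounts(c, d, tg, tx, tb)


def random_ordinal_pair(rng: np.random.Generator, n_categories: int,
                        n: int = 30) -> PairedSeries:
    """A random non-degenerate item/score pair with heavy ties."""
    while True:
        g = rng.integers(0, n_categories, size=n)
        x = rng.integers(0, 8, size=n).astype(float) + g * rng.uniform(0, 1.5)
        if np.ptp(g) > 0 and np.ptp(x) > 0:
            return PairedSeries(g, x)
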