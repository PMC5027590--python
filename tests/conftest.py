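import numpy as np
import pandas as pd
import pytest

import daccspot as ds
from daccspot.properties import CLASS_LABELS, PropertyTable


@pytest.fixture(scope="session")
def table() -> PropertyTable:
    return ds.default_table()


@pytest.fixture(scope="session")
def std_table() -> PropertyTable:
    return ds.default_table(standardized=True)


def subtable(table: PropertyTable, names: list[str]) -> PropertyTable:
    """Property table restricted to a subset of rows (for small-N checks)."""
    return PropertyTable(table.table.loc[names], standardized=table.standardized)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def brute_force_dacc(sequence: str, config: ds.EncodingConfig) -> np.ndarray:
    """Direct per-term transcription of the DAC/DCC definitions.

    Pure-python loops over positions and properties; shares nothing with the
    vectorized encoder except the property table lookups.
    """
    tab = config.table
    props = tab.property_names
    L = len(sequence)
    profiles = {
        p: [tab.value(p, sequence[i : i + 2]) for i in range(L - 1)] for p in props
    }
    means = {p: sum(v) / len(v) for p, v in profiles.items()}

    def cov(p1: str, p2: str, lag: int) -> float:
        total = 0.0
        n = L - 1 - lag
        for i in range(n):
            total += (profiles[p1][i] - means[p1]) * (profiles[p2][i + lag] - means[p2])
        return total / n

    out = []
    for p in props:
        for lag in range(1, config.lag + 1):
            out.append(cov(p, p, lag))
    for p1 in props:
        for p2 in props:
            if p2 == p1:
                continue
            for lag in range(1, config.lag + 1):
                out.append(cov(p1, p2, lag))
    return np.array(out)


@pytest.fixture(scope="session")
def small_planted_dataset():
    """200-sequence synthetic set with the default planted signal, encoded."""
    records = ds.generate(ds.SyntheticSpec(n_pos=100, n_neg=100, seed=11))
    config = ds.EncodingConfig(standardize_properties=True)
    matrix, skipped = ds.encode_batch(
        [(r.id, r.sequence) for r in records],
        config,
        labels=[r.label for r in records],
    )
    assert not skipped
    return matrix


def two_cluster_data(n: int = 50, d: int = 8, sep: float = 6.0, seed: int = 0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n, d))
    X[:n, 0] += sep
    y = np.array([1] * n + [-1] * n)
    return X, y
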