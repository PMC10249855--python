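import numpy as np
import pandas as pd
import pytest

from mhnet import (CorrelationNetwork, IndicatorPanel, Partition,
                   SignedLayers, builtin_grouping)


def planted_assignment(n_groups: int, per_group: int) -> dict[str, str]:
    """Unit -> group map with equal-size planted groups."""
    return {f"U{g:02d}{i:02d}": f"g{g}"
            for g in range(n_groups) for i in range(per_group)}


def planted_partition(assignment: dict[str, str]) -> Partition:
    units = sorted(assignment)
    labels = {g: k for k, g in enumerate(dict.fromkeys(assignment[u] for u in units))}
    return Partition(units, [labels[assignment[u]] for u in units])


def block_matrix(sizes, within, between, rng=None, noise=0.0) -> np.ndarray:
    """Symmetric unit-diagonal matrix with planted block structure."""
    n = sum(sizes)
    P = np.full((n, n), float(between))
    start = 0
    for s in sizes:
        P[start:start + s, start:start + s] = within
        start += s
    if noise:
        jitter = rng.uniform(-noise, noise, size=(n, n))
        P += (jitter + jitter.T) / 2
    P = np.clip(P, -1.0, 1.0)
    np.fill_diagonal(P, 1.0)
    return P


def network_from_matrix(P: np.ndarray) -> CorrelationNetwork:
    units = [f"U{i:02d}" for i in range(P.shape[0])]
    dates = (pd.Timestamp("2021-03-02"), pd.Timestamp("2021-03-31"))
    return CorrelationNetwork(units, P, dates)


def random_network(rng: np.random.Generator, n: int) -> CorrelationNetwork:
    """Valid random correlation matrix via a random Gram matrix."""
    X = rng.standard_normal((n, max(n + 2, 10)))
    P = np.corrcoef(X)
    return network_from_matrix(P)


def random_panel(rng: np.random.Generator, n_units: int,
                 n_days: int) -> IndicatorPanel:
    return IndicatorPanel(
        unit_ids=[f"U{i:02d}" for i in range(n_units)],
        dates=pd.date_range("2021-03-02", periods=n_days, freq="D"),
        values=rng.standard_normal((n_units, n_days)) * 3 + 20,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20210302)


@pytest.fixture(scope="session")
def region_grouping():
    return builtin_grouping("region")
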