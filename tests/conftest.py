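import numpy as np
import pytest

from netdiff import LabeledDataset, NetworkSpec, fixture_network, random_connected_network


@pytest.fixture
def triangle() -> NetworkSpec:
    return NetworkSpec.from_pairs([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def small_net() -> NetworkSpec:
    """Shipped 10-vertex / 21-edge study-scale topology."""
    return fixture_network("small")


@pytest.fixture
def large_net() -> NetworkSpec:
    """Shipped 20-vertex / 45-edge study-scale topology."""
    return fixture_network("large")


def random_dataset(
    n: int = 30, m: int = 4, seed: int = 0, n_case: int | None = None
) -> tuple[LabeledDataset, NetworkSpec]:
    """A generic correlated dataset paired with a random connected network."""
    rng = np.random.default_rng(seed)
    k = min(m, m * (m - 1) // 2)
    net = random_connected_network(m, k, seed=seed)
    x = rng.standard_normal((n, m)) + 0.4 * rng.standard_normal((n, 1))
    n_case = n // 2 if n_case is None else n_case
    y = np.zeros(n, dtype=int)
    y[rng.choice(n, size=n_case, replace=False)] = 1
    return LabeledDataset(x, y, net.vertex_names), net


@pytest.fixture
def dataset_30x4() -> tuple[LabeledDataset, NetworkSpec]:
    return random_dataset(n=30, m=4, seed=7)
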