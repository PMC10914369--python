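import numpy as np
import pytest

from netflex import BipartiteNetwork, NetworkSeries


@pytest.fixture
def toy_series():
    """Two-realization series used throughout the hand-derived examples."""
    return NetworkSeries(
        [
            ("r1", BipartiteNetwork({("A", "x"): 1, ("B", "x"): 1, ("B", "y"): 1})),
            ("r2", BipartiteNetwork({("A", "x"): 1, ("B", "x"): 1})),
        ]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240305)


def random_series(rng, n_consumers=10, n_resources=30, n_realizations=4, p_edge=0.08):
    """Random integer-weighted series; every realization nonempty."""
    consumers = [f"C{i:02d}" for i in range(n_consumers)]
    resources = [f"r{i:02d}" for i in range(n_resources)]
    realizations = []
    for t in range(n_realizations):
        while True:
            edges = {
                (c, r): float(rng.integers(1, 8))
                for c in consumers
                for r in resources
                if rng.random() < p_edge
            }
            if edges:
                break
        realizations.append((f"t{t}", BipartiteNetwork(edges)))
    return NetworkSeries(realizations)
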