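import numpy as np
import pytest

import taskcomm as tc


@pytest.fixture(scope="session")
def default_truth() -> tc.GroundTruth:
    """100 nodes, 4 stable blocks of 22, 12 movers."""
    return tc.make_ground_truth(seed=0)


@pytest.fixture(scope="session")
def blocks_truth() -> tc.GroundTruth:
    """100 nodes, 4 equal blocks, no movers."""
    return tc.make_ground_truth(n_movers=0, seed=0)


@pytest.fixture(scope="session")
def node_table_100() -> "object":
    return tc.make_node_table(100, [f"RSN{k}" for k in range(10)], seed=3)


@pytest.fixture(scope="session")
def planted_network(blocks_truth, node_table_100) -> tc.ConnectivityMatrix:
    """Filtered Fisher-z network from one planted-block beta series."""
    series = tc.plant_beta_series(blocks_truth, n_trials=40, seed=7)
    return tc.series_to_network(series["space_encoding"], node_table_100)


def random_filtered_matrix(n: int, seed: int) -> tc.ConnectivityMatrix:
    """Random non-negative symmetric zero-diagonal matrix (test helper)."""
    rng = np.random.default_rng(seed)
    w = np.abs(rng.normal(0.3, 0.2, (n, n)))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return tc.ConnectivityMatrix(weights=w, node_ids=tuple(range(n)))
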