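import logging

import numpy as np
import pytest

import topodiff as td


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    # tests assert on behavior, not log chatter; warnings stay capturable
    logging.getLogger("topodiff").setLevel(logging.DEBUG)
    yield


@pytest.fixture(scope="session")
def small_config():
    return td.SimConfig(n_genes=120, n_blocks=6, block_size=15,
                        n_samples_per_group=30, within_block_corr=0.8,
                        n_divergent=12, seed=11)


@pytest.fixture(scope="session")
def region_pair(small_config):
    return td.simulate_region_pair(small_config)


@pytest.fixture(scope="session")
def network_pair(region_pair):
    m1, m2, truth = region_pair
    return td.build_network(m1), td.build_network(m2), truth


def random_network(n, p, seed, ensure_connected=True):
    """Random binary network; a cycle backbone guarantees no isolated nodes."""
    rng = np.random.default_rng(seed)
    adj = (rng.random((n, n)) < p).astype(np.uint8)
    adj = np.triu(adj, 1)
    adj = adj + adj.T
    if ensure_connected:
        for i in range(n):
            adj[i, (i + 1) % n] = adj[(i + 1) % n, i] = 1
    np.fill_diagonal(adj, 0)
    genes = [f"g{i:04d}" for i in range(n)]
    return td.CoexprNetwork(genes, adj)
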