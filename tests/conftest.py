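import networkx as nx
import numpy as np
import pytest

from casgrn.datasets_io import DiscreteDataset
from casgrn.synthetic import (
    BayesianNetwork,
    collider_fixture,
    forward_sample,
    random_cpts,
    random_dag,
)


@pytest.fixture(scope="session")
def collider_bn() -> BayesianNetwork:
    return collider_fixture()


@pytest.fixture(scope="session")
def collider_data(collider_bn) -> DiscreteDataset:
    return forward_sample(collider_bn, 5000, seed=11)


def make_chain_bn(n_nodes: int = 5, seed: int = 0) -> BayesianNetwork:
    """Chain A->B->C->... with strongly dependent ternary CPTs."""
    names = [chr(ord("A") + i) for i in range(n_nodes)]
    dag = nx.DiGraph()
    dag.add_nodes_from(names)
    dag.add_edges_from(zip(names, names[1:]))
    rng = np.random.default_rng(seed)
    cards = {v: 3 for v in names}
    cpts = {names[0]: {"parents": (), "table": np.array([[0.3, 0.4, 0.3]])}}
    for prev, v in zip(names, names[1:]):
        # near-permutation rows: child strongly tracks its parent
        rows = []
        for s in range(3):
            row = np.full(3, 0.1)
            row[(s + rng.integers(0, 3)) % 3] = 0.8
            rows.append(row)
        cpts[v] = {"parents": (prev,), "table": np.array(rows)}
    return BayesianNetwork(dag=dag, cardinalities=cards, cpts=cpts)


@pytest.fixture(scope="session")
def chain_bn() -> BayesianNetwork:
    return make_chain_bn(5, seed=4)


def random_dataset(n_vars: int, n_samples: int, seed: int) -> DiscreteDataset:
    """Small random dataset from a random sparse network."""
    dag = random_dag(n_vars, min(2.0, n_vars - 1.0), 3, seed=seed)
    bn = random_cpts(dag, 3, 0.5, seed=seed + 1)
    return forward_sample(bn, n_samples, seed=seed + 2)
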