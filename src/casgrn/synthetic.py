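"""Ground-truth network and data generators.

Everything downstream — mutual-information ranking, breakpoint detection,
score search — is exercised against data whose generating network is known.
This module builds random sparse DAGs at gene-regulatory-network scale,
equips them with Dirichlet-drawn conditional probability tables, draws
records by ancestral sampling, and plants breakpoints in synthetic sorted
MI vectors.

All randomness flows through an explicitly passed seed; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .datasets_io import DiscreteDataset

__all__ = [
    "BayesianNetwork",
    "random_dag",
    "random_cpts",
    "forward_sample",
    "collider_fixture",
    "planted_breakpoint_vector",
]


@dataclass
class BayesianNetwork:
    """A DAG plus per-node conditional probability tables.

    ``cpts[v]`` is ``{"parents": tuple of parent names, "table": array}``
    where ``table`` has one row per parent configuration (row index =
    ``ravel_multi_index`` of parent states in the stored parent order) and
    one column per state of ``v``.
    """

    dag: nx.DiGraph
    cardinalities: dict[str, int]
    cpts: dict[str, dict]
    state_names: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("network graph must be acyclic")
        for v in self.dag.nodes:
            if v not in self.cpts:
                raise ValueError(f"node {v!r} has no CPT")
            cpt = self.cpts[v]
            parents = cpt["parents"]
            if set(parents) != set(self.dag.predecessors(v)):
                raise ValueError(f"node {v!r}: CPT parents disagree with DAG")
            r = self.cardinalities[v]
            q = int(np.prod([self.cardinalities[p] for p in parents])) if parents else 1
            table = np.asarray(cpt["table"], dtype=float)
            if table.shape != (q, r):
                raise ValueError(
                    f"node {v!r}: CPT shape {table.shape}, expected {(q, r)}"
                )
            if (np.abs(table.sum(axis=1) - 1.0) > 1e-12).any():
                raise ValueError(f"node {v!r}: CPT rows must sum to 1")
            cpt["table"] = table

    @property
    def nodes(self) -> list[str]:
        return sorted(self.dag.nodes)

    def parent_config_index(self, v: str, record: dict[str, int]) -> int:
        parents = self.cpts[v]["parents"]
        if not parents:
            return 0
        cards = [self.cardinalities[p] for p in parents]
        return int(np.ravel_multi_index([record[p] for p in parents], cards))


def random_dag(
    n_nodes: int, mean_degree: float, max_indegree: int = 4, seed: int = 0
) -> nx.DiGraph:
    """Sparse random DAG with expected ``n_nodes * mean_degree / 2`` edges.

    Edges are drawn independently with probability ``mean_degree/(n_nodes-1)``
    from lower to higher position in a random topological order; a node's
    surplus parents beyond ``max_indegree`` are dropped at random.  Node
    labels g001.. are shuffled relative to the topological order so label
    order carries no structural information.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not 0 < mean_degree < n_nodes:
        raise ValueError("mean_degree must lie in (0, n_nodes)")
    if max_indegree < 1:
        raise ValueError("max_indegree must be >= 1")
    rng = np.random.default_rng(seed)
    p_edge = mean_degree / (n_nodes - 1)
    width = len(str(n_nodes))
    labels = [f"g{i + 1:0{width}d}" for i in range(n_nodes)]
    order = rng.permutation(n_nodes)  # order[i] = label index at topo position i
    g = nx.DiGraph()
    g.add_nodes_from(labels)
    for j in range(1, n_nodes):
        mask = rng.random(j) < p_edge
        parents = np.flatnonzero(mask)
        if len(parents) > max_indegree:
            parents = rng.choice(parents, size=max_indegree, replace=False)
        for i in parents:
            g.add_edge(labels[order[i]], labels[order[j]])
    return g


def random_cpts(
    dag: nx.DiGraph, cardinality: int = 3, concentration: float = 0.5, seed: int = 0
) -> BayesianNetwork:
    """Attach CPTs with every row drawn from a symmetric Dirichlet.

    Low concentration (default 0.5) gives peaked rows, i.e. strong and
    learnable parent-child dependencies; large concentration approaches
    uniform rows (no signal).
    """
    if cardinality < 2:
        raise ValueError("cardinality must be >= 2")
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    cards = {v: cardinality for v in dag.nodes}
    cpts = {}
    for v in sorted(dag.nodes):
        parents = tuple(sorted(dag.predecessors(v)))
        q = int(np.prod([cards[p] for p in parents])) if parents else 1
        table = rng.dirichlet([concentration] * cardinality, size=q)
        cpts[v] = {"parents": parents, "table": table}
    return BayesianNetwork(dag=dag.copy(), cardinalities=cards, cpts=cpts)


def forward_sample(bn: BayesianNetwork, n_samples: int, seed: int = 0) -> DiscreteDataset:
    """Ancestral sampling: draw each node given its parents in topological order."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not nx.is_directed_acyclic_graph(bn.dag):
        raise ValueError("cannot forward-sample a cyclic graph")
    rng = np.random.default_rng(seed)
    topo = list(nx.lexicographical_topological_sort(bn.dag))
    names = sorted(bn.dag.nodes)
    col = {v: i for i, v in enumerate(names)}
    data = np.zeros((n_samples, len(names)), dtype=np.int64)
    for v in topo:
        cpt = bn.cpts[v]
        parents = cpt["parents"]
        table = cpt["table"]
        if not parents:
            rows = np.zeros(n_samples, dtype=np.int64)
        else:
            cards = [bn.cardinalities[p] for p in parents]
            rows = np.ravel_multi_index(
                [data[:, col[p]] for p in parents], cards
            )
        u = rng.random(n_samples)
        cum = np.cumsum(table, axis=1)
        data[:, col[v]] = (u[:, None] > cum[rows]).sum(axis=1)
    cards_vec = np.array([bn.cardinalities[v] for v in names])
    return DiscreteDataset(names, cards_vec, data)


def collider_fixture() -> BayesianNetwork:
    """The canonical common-effect network X -> Z <- Y, Z -> W.

    X and Y are marginally independent binary causes; Z responds strongly to
    the pair (close to an OR gate with 5% flip noise) and W copies Z with 10%
    noise.  The strong CPTs make MI(X,Z) and MI(Y,Z) large while MI(X,Y)
    stays at small-sample noise level — the configuration candidate
    auto-selection is built to prune.
    """
    dag = nx.DiGraph([("X", "Z"), ("Y", "Z"), ("Z", "W")])
    cards = {"X": 2, "Y": 2, "Z": 2, "W": 2}
    cpts = {
        "X": {"parents": (), "table": np.array([[0.5, 0.5]])},
        "Y": {"parents": (), "table": np.array([[0.5, 0.5]])},
        # rows ordered by (X, Y) via ravel_multi_index: (0,0),(0,1),(1,0),(1,1)
        "Z": {
            "parents": ("X", "Y"),
            "table": np.array(
                [[0.95, 0.05], [0.05, 0.95], [0.05, 0.95], [0.05, 0.95]]
            ),
        },
        "W": {"parents": ("Z",), "table": np.array([[0.9, 0.1], [0.1, 0.9]])},
    }
    return BayesianNetwork(dag=dag, cardinalities=cards, cpts=cpts)


def planted_breakpoint_vector(
    m: int,
    k_true: int,
    mu1: float,
    sigma1: float,
    mu2: float,
    sigma2: float,
    seed: int = 0,
) -> tuple[np.ndarray, int, bool]:
    """Sorted vector of ``k_true`` left-population and ``m - k_true`` right-
    population Gaussian draws, clamped at 0 (MI is non-negative).

    Returns ``(values, separator, has_true_break)``.  The separator is
    recomputed after sorting as the length of the pure left-population
    prefix of the sorted vector (overlapping populations can interleave, in
    which case the prefix is shorter than ``k_true``; with clean separation
    it equals ``k_true`` exactly).  When the two populations are identical
    there is no true break: the nominal ``k_true`` is returned with
    ``has_true_break = False``.
    """
    if not 1 <= k_true < m:
        raise ValueError("need 1 <= k_true < m")
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValueError("sigmas must be > 0")
    rng = np.random.default_rng(seed)
    left = rng.normal(mu1, sigma1, size=k_true)
    right = rng.normal(mu2, sigma2, size=m - k_true)
    values = np.clip(np.concatenate([left, right]), 0.0, None)
    origin = np.concatenate([np.zeros(k_true, int), np.ones(m - k_true, int)])
    order = np.argsort(values, kind="stable")
    values = values[order]
    origin = origin[order]
    if mu1 == mu2 and sigma1 == sigma2:
        return values, k_true, False
    right_positions = np.flatnonzero(origin == 1)
    separator = int(right_positions[0]) if len(right_positions) else m
    return values, separator, True
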