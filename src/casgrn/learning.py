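"""Score-and-search structure learning.

Four engines share one BDeu scoring core:

* ``greedy_search`` — add-only hill climbing over an arbitrary allowed-edge
  space; with the full space it is the unrestricted benchmark.
* ``cas_g`` — the same global greedy restricted to the candidate-set edge
  space (u→v allowed iff u ∈ C(v) or v ∈ C(u)).
* ``cas_l`` — local learning: a greedy search per node over its own edge
  set E(v) = {(v,u), (u,v) : u ∈ C(v)}, followed by a cycle-free merge of
  all local edges in descending order of their acceptance-time score gain.
* ``exhaustive_search`` — enumeration of every labeled DAG on ≤ 4 nodes;
  the exact-optimum oracle for tiny instances.

All searches start from the empty graph, accept only strictly
score-improving edges, and are fully deterministic (ties break
lexicographically).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .cas import CandidateSets, cas_all
from .datasets_io import DiscreteDataset
from .scoring import ScoreCache, bdeu_family_score, delta_add, total_score

__all__ = [
    "EdgeSpace",
    "LocalStructure",
    "LearnResult",
    "introduces_cycle",
    "full_edge_space",
    "greedy_search",
    "cas_g",
    "learn_local",
    "pool_local_edges",
    "merge_scored_edges",
    "cas_l",
    "exhaustive_search",
]


@dataclass
class EdgeSpace:
    """The set of directed edges a search may consider."""

    allowed: set[tuple[str, str]]

    def __post_init__(self) -> None:
        for u, v in self.allowed:
            if u == v:
                raise ValueError(f"self-loop {u!r} in edge space")

    def __len__(self) -> int:
        return len(self.allowed)

    def __contains__(self, edge) -> bool:
        return edge in self.allowed


@dataclass
class LocalStructure:
    """Edges accepted while greedily learning around one center node."""

    center: str
    scored_edges: list[tuple[tuple[str, str], float]] = field(default_factory=list)


@dataclass
class LearnResult:
    graph: nx.DiGraph
    score: float
    trace: list[tuple[tuple[str, str], float, bool]] = field(default_factory=list)
    space_size: int | None = None
    method: str = ""

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges())


def introduces_cycle(g: nx.DiGraph, edge: tuple[str, str]) -> bool:
    """Would adding u→v create a directed cycle?  True iff v already
    reaches u."""
    u, v = edge
    if u == v:
        raise ValueError("self-loop query")
    if u not in g or v not in g:
        raise ValueError("edge endpoints must be nodes of the graph")
    return nx.has_path(g, v, u)


def full_edge_space(names) -> EdgeSpace:
    """All ordered pairs — the unrestricted benchmark space."""
    return EdgeSpace({(u, v) for u in names for v in names if u != v})


def greedy_search(
    d: DiscreteDataset,
    space: EdgeSpace,
    ess: float = 1.0,
    cache: ScoreCache | None = None,
    max_parents: int | None = None,
    compute_score: bool = True,
    initial_deltas: dict[tuple[str, str], float] | None = None,
    moves: tuple[str, ...] = ("add",),
) -> LearnResult:
    """Greedy hill climbing from the empty graph.

    With the default add-only moveset, each iteration scores every allowed,
    absent, non-cycle-inducing edge by its BDeu gain, adds the single best
    strictly positive one, and stops when none remains.  Add gains are
    cached per child and recomputed only for the child whose family last
    changed; ``initial_deltas`` may supply precomputed empty-graph gains
    (the local learner shares one such table across all per-node
    searches).  Optional ``delete`` and ``reverse`` moves extend the
    moveset (reversal helps recover misoriented v-structures, at the cost
    of leaving the pure add-only behavior).
    """
    bad = set(moves) - {"add", "delete", "reverse"}
    if bad:
        raise ValueError(f"unknown moves {sorted(bad)}")
    if cache is None:
        cache = ScoreCache()

    def family(child: str, parents: set[str]) -> float:
        return bdeu_family_score(d, child, parents, ess, cache).score

    g = nx.DiGraph()
    g.add_nodes_from(d.variable_names)
    trace: list[tuple[tuple[str, str], float, bool]] = []
    allowed = sorted(space.allowed)
    if initial_deltas is None:
        deltas = {e: delta_add(d, g, e, ess, cache) for e in allowed}
    else:
        deltas = {e: initial_deltas[e] for e in allowed}
    while True:
        best: tuple[str, tuple[str, str], float] | None = None

        def consider(kind, edge, delta):
            nonlocal best
            if delta > 0 and (best is None or delta > best[2]):
                best = (kind, edge, delta)

        for e in allowed:
            if g.has_edge(*e):
                continue
            delta = deltas[e]
            if delta <= 0 or (best is not None and delta <= best[2]):
                continue
            if max_parents is not None and g.in_degree(e[1]) >= max_parents:
                continue
            if introduces_cycle(g, e):
                continue
            consider("add", e, delta)
        if "delete" in moves or "reverse" in moves:
            for u, v in sorted(g.edges()):
                parents = set(g.predecessors(v))
                base = family(v, parents)
                gain_del = family(v, parents - {u}) - base
                if "delete" in moves:
                    consider("delete", (u, v), gain_del)
                if "reverse" in moves and (v, u) in space:
                    g.remove_edge(u, v)
                    cyclic = introduces_cycle(g, (v, u))
                    g.add_edge(u, v)
                    if not cyclic:
                        u_parents = set(g.predecessors(u))
                        gain_rev = gain_del + family(u, u_parents | {v}) - family(u, u_parents)
                        consider("reverse", (u, v), gain_rev)
        if best is None:
            break
        kind, edge, delta = best
        u, v = edge
        touched = {v}
        if kind == "add":
            g.add_edge(u, v)
        elif kind == "delete":
            g.remove_edge(u, v)
        else:
            g.remove_edge(u, v)
            g.add_edge(v, u)
            touched.add(u)
        trace.append((edge if kind != "reverse" else (v, u), delta, True))
        for e in allowed:
            if e[1] in touched and not g.has_edge(*e):
                deltas[e] = delta_add(d, g, e, ess, cache)
    return LearnResult(
        graph=g,
        score=total_score(d, g, ess, cache) if compute_score else float("nan"),
        trace=trace,
        space_size=len(space),
        method="greedy",
    )


def cas_g(
    d: DiscreteDataset,
    ess: float = 1.0,
    cands: CandidateSets | None = None,
    max_parents: int | None = None,
    moves: tuple[str, ...] = ("add",),
) -> LearnResult:
    """Global greedy search restricted to the candidate-set edge space."""
    if cands is None:
        cands = cas_all(d)
    space = EdgeSpace(cands.allowed_edges())
    res = greedy_search(d, space, ess, max_parents=max_parents, moves=moves)
    res.method = "casg"
    return res


def learn_local(
    d: DiscreteDataset,
    v: str,
    cands,
    ess: float = 1.0,
    cache: ScoreCache | None = None,
    initial_deltas: dict[tuple[str, str], float] | None = None,
) -> LocalStructure:
    """Greedy search over E(v) = {(v,u), (u,v) : u ∈ C(v)} around node v."""
    if v in set(cands):
        raise ValueError(f"{v!r} cannot be its own candidate")
    space = EdgeSpace({(v, u) for u in cands} | {(u, v) for u in cands})
    res = greedy_search(
        d, space, ess, cache, compute_score=False, initial_deltas=initial_deltas
    )
    return LocalStructure(
        center=v,
        scored_edges=[(e, delta) for e, delta, acc in res.trace if acc],
    )


def pool_local_edges(locals_) -> dict[tuple[str, str], float]:
    """Pool scored edges from local structures, deduplicating identical
    edges by keeping the larger gain."""
    pooled: dict[tuple[str, str], float] = {}
    for local in locals_:
        for edge, delta in local.scored_edges:
            if edge not in pooled or delta > pooled[edge]:
                pooled[edge] = delta
    return pooled


def merge_scored_edges(names, pooled: dict[tuple[str, str], float]):
    """Cycle-free merge: accept pooled edges in descending gain order
    (ties lexicographic), skipping any edge that closes a cycle or whose
    reverse was already accepted.  Returns (graph, trace)."""
    g = nx.DiGraph()
    g.add_nodes_from(names)
    trace: list[tuple[tuple[str, str], float, bool]] = []
    for edge, delta in sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0])):
        u, v = edge
        if g.has_edge(v, u) or introduces_cycle(g, edge):
            trace.append((edge, delta, False))
            continue
        g.add_edge(u, v)
        trace.append((edge, delta, True))
    return g, trace


def cas_l(
    d: DiscreteDataset,
    ess: float = 1.0,
    cands: CandidateSets | None = None,
) -> LearnResult:
    """Local learning: per-node local structures merged cycle-free.

    Pooled edges are deduplicated (an edge found by two local searches keeps
    its larger gain), sorted by gain descending, then accepted one by one
    skipping any edge that would close a cycle or whose reverse was already
    accepted.  The per-node searches are independent, so their order cannot
    affect the pooled result.
    """
    if cands is None:
        cands = cas_all(d)
    cache = ScoreCache()
    # all local searches start from the empty graph, so their initial edge
    # gains coincide on the shared space and are computed once
    empty = nx.DiGraph()
    empty.add_nodes_from(d.variable_names)
    shared_deltas = {
        e: delta_add(d, empty, e, ess, cache) for e in sorted(cands.allowed_edges())
    }
    locals_ = [
        learn_local(d, v, cands[v], ess, cache, shared_deltas)
        for v in d.variable_names
    ]
    pooled = pool_local_edges(locals_)
    g, trace = merge_scored_edges(d.variable_names, pooled)
    return LearnResult(
        graph=g,
        score=total_score(d, g, ess, cache),
        trace=trace,
        space_size=len(cands.allowed_edges()),
        method="casl",
    )


def _all_dags(names):
    """Yield every labeled DAG on the given nodes (feasible for ≤ 4)."""
    pairs = [(u, v) for u in names for v in names if u != v]
    for mask in range(1 << len(pairs)):
        g = nx.DiGraph()
        g.add_nodes_from(names)
        g.add_edges_from(p for i, p in enumerate(pairs) if mask >> i & 1)
        if nx.is_directed_acyclic_graph(g):
            yield g


def exhaustive_search(d: DiscreteDataset, ess: float = 1.0) -> LearnResult:
    """Exact optimum by enumerating all labeled DAGs; refuses > 4 variables."""
    if d.n_variables > 4:
        raise ValueError("exhaustive search is limited to <= 4 variables")
    cache = ScoreCache()
    best_g, best_s = None, -np.inf
    for g in _all_dags(d.variable_names):
        s = total_score(d, g, ess, cache)
        if s > best_s:
            best_g, best_s = g, s
    return LearnResult(graph=best_g, score=float(best_s), method="exhaustive")
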