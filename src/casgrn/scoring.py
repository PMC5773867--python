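"""BDeu (Bayesian Dirichlet equivalent uniform) family scoring.

The score of a child v with parent set Pa is the log marginal likelihood of
the child's data column under a Dirichlet prior with equivalent sample size
``ess`` spread uniformly over the r·q parameter cells (r = child
cardinality, q = number of parent configurations):

    score(v | Pa) = Σ_j [ lnΓ(α_j) − lnΓ(α_j + N_j)
                          + Σ_k ( lnΓ(α_jk + N_jk) − lnΓ(α_jk) ) ],

with α_jk = ess/(r·q), α_j = ess/q, N_jk the count of (parent config j,
child state k) and N_j = Σ_k N_jk.  Parent configurations never observed
contribute exactly 0 and are skipped.  The total graph score decomposes as
the sum of family scores, which is what makes greedy edge moves cheap: one
edge change touches one family term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.special import gammaln

from .datasets_io import DiscreteDataset

__all__ = ["FamilyScore", "ScoreCache", "bdeu_family_score", "total_score", "delta_add"]


@dataclass(frozen=True)
class FamilyScore:
    child: str
    parents: frozenset[str]
    score: float
    ess: float


class ScoreCache:
    """Memo for family scores, keyed order-insensitively on the parent set."""

    def __init__(self) -> None:
        self._store: dict[tuple[str, frozenset[str]], FamilyScore] = {}
        self.hits = 0
        self.misses = 0

    def get(self, child: str, parents: frozenset[str]) -> FamilyScore | None:
        fs = self._store.get((child, parents))
        if fs is not None:
            self.hits += 1
        return fs

    def put(self, fs: FamilyScore) -> None:
        self.misses += 1
        self._store[(fs.child, fs.parents)] = fs


def bdeu_family_score(
    d: DiscreteDataset,
    child: str,
    parents,
    ess: float = 1.0,
    cache: ScoreCache | None = None,
) -> FamilyScore:
    """BDeu log marginal likelihood (nats) of one child/parent-set family."""
    if ess <= 0:
        raise ValueError("ess must be > 0")
    parents = frozenset(parents)
    if child in parents:
        raise ValueError(f"child {child!r} cannot be its own parent")
    if cache is not None:
        hit = cache.get(child, parents)
        if hit is not None and hit.ess == ess:
            return hit

    ci = d.index(child)
    r = int(d.cardinalities[ci])
    parent_list = sorted(parents)
    p_idx = [d.index(p) for p in parent_list]
    p_cards = [int(d.cardinalities[i]) for i in p_idx]
    q = math.prod(p_cards) if parent_list else 1

    if parent_list:
        cfg = np.ravel_multi_index([d.data[:, i] for i in p_idx], p_cards)
    else:
        cfg = np.zeros(d.n_samples, dtype=np.int64)
    counts = np.bincount(cfg * r + d.data[:, ci], minlength=q * r).reshape(q, r)
    n_j = counts.sum(axis=1)
    observed = n_j > 0
    a_jk = ess / (r * q)
    a_j = ess / q
    score = float(
        np.sum(gammaln(a_j) - gammaln(a_j + n_j[observed]))
        + np.sum(gammaln(a_jk + counts[observed]) - gammaln(a_jk))
    )
    fs = FamilyScore(child=child, parents=parents, score=score, ess=ess)
    if cache is not None:
        cache.put(fs)
    return fs


def total_score(
    d: DiscreteDataset,
    g: nx.DiGraph,
    ess: float = 1.0,
    cache: ScoreCache | None = None,
) -> float:
    """Decomposable total: Σ over nodes of their family score under ``g``."""
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("graph must be acyclic")
    return float(
        sum(
            bdeu_family_score(d, v, set(g.predecessors(v)), ess, cache).score
            for v in d.variable_names
        )
    )


def delta_add(
    d: DiscreteDataset,
    g: nx.DiGraph,
    edge: tuple[str, str],
    ess: float = 1.0,
    cache: ScoreCache | None = None,
) -> float:
    """Score change from adding u→v: only v's family term moves."""
    u, v = edge
    if u == v:
        raise ValueError("self-loop")
    if g.has_edge(u, v):
        raise ValueError(f"edge {u}->{v} already present")
    parents = set(g.predecessors(v))
    before = bdeu_family_score(d, v, parents, ess, cache).score
    after = bdeu_family_score(d, v, parents | {u}, ess, cache).score
    return float(after - before)
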