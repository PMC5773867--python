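"""Model/Results front end for candidate selection and structure learning.

Two model classes wrap the functional core in the fit-then-inspect idiom:
construct the model from data, call :meth:`fit`, and read estimates,
diagnostics and a ``summary()`` table off the returned results object.

>>> bn = collider_fixture()
>>> data = forward_sample(bn, 2000, seed=7)
>>> res = StructureLearner(data, method="casg").fit()
>>> sorted(res.graph.edges())          # doctest: +SKIP
[('X', 'Z'), ('Y', 'Z'), ('Z', 'W')]
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from . import learning
from .cas import CandidateSets, cas_all
from .datasets_io import DiscreteDataset, ExpressionMatrix, kmeans_discretize
from .evaluation import candidate_confusion, metrics, shd, structure_confusion
from .mi import mi_matrix

__all__ = [
    "CandidateSelection",
    "CandidateSelectionResults",
    "StructureLearner",
    "StructureResults",
]


def _as_discrete(data, levels: int = 3, seed: int = 0) -> DiscreteDataset:
    if isinstance(data, DiscreteDataset):
        return data
    if isinstance(data, ExpressionMatrix):
        return kmeans_discretize(data, levels=levels, seed=seed)
    if isinstance(data, pd.DataFrame):
        x = ExpressionMatrix([str(c) for c in data.columns], data.to_numpy(float))
        return kmeans_discretize(x, levels=levels, seed=seed)
    raise TypeError(f"unsupported data type {type(data).__name__}")


class CandidateSelection:
    """Candidate auto-selection model: per-node breakpoint detection on
    sorted mutual-information rankings.

    Parameters
    ----------
    data : DiscreteDataset, ExpressionMatrix or DataFrame
        Samples x variables.  Continuous input is discretized by per-gene
        k-means first.
    levels, seed : int
        Discretization settings, used only for continuous input.
    """

    def __init__(self, data, levels: int = 3, seed: int = 0):
        self.data = _as_discrete(data, levels, seed)

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kw) -> "CandidateSelection":
        return cls(frame, **kw)

    def fit(self) -> "CandidateSelectionResults":
        mim = mi_matrix(self.data)
        cands = cas_all(self.data, mim)
        return CandidateSelectionResults(model=self, mi=mim, candidate_sets=cands)


@dataclass
class CandidateSelectionResults:
    model: CandidateSelection
    mi: object
    candidate_sets: CandidateSets

    @property
    def mean_candidate_count(self) -> float:
        sizes = [len(s) for s in self.candidate_sets.candidates.values()]
        return sum(sizes) / len(sizes)

    @property
    def space_reduction(self) -> float:
        """Allowed-edge space as a fraction of the full n(n−1) space."""
        n = self.model.data.n_variables
        return len(self.candidate_sets.allowed_edges()) / (n * (n - 1))

    def recall_against(self, truth: nx.DiGraph) -> tuple[float, float]:
        """(mean per-node recall, mean candidate count) against a gold
        standard."""
        _, mean_recall, mean_size = candidate_confusion(truth, self.candidate_sets)
        return mean_recall, mean_size

    def summary(self) -> pd.DataFrame:
        rows = []
        for v in sorted(self.candidate_sets.candidates):
            bp = self.candidate_sets.breakpoints[v]
            rows.append(
                {
                    "node": v,
                    "n_candidates": len(self.candidate_sets[v]),
                    "breakpoint_k": bp.k,
                    "Q": bp.q,
                    "significant": bp.significant,
                    "left_mu": bp.left.mu,
                    "right_mu": bp.right.mu,
                }
            )
        return pd.DataFrame(rows).set_index("node")


class StructureLearner:
    """Bayesian-network structure model fitted by BDeu score search.

    Parameters
    ----------
    data : DiscreteDataset, ExpressionMatrix or DataFrame
    method : {"casg", "casl", "greedy"}
        Restricted global greedy, restricted local learning, or the
        unrestricted greedy benchmark.
    ess : float
        BDeu equivalent sample size (Dirichlet prior strength).
    moves : tuple of str
        Hill-climbing moveset for the global searches; ``("add",)`` by
        default, optionally including ``"delete"`` and ``"reverse"``.
        Ignored by the local learner.
    """

    def __init__(self, data, method: str = "casg", ess: float = 1.0,
                 levels: int = 3, seed: int = 0,
                 moves: tuple[str, ...] = ("add",),
                 max_parents: int | None = None):
        if method not in {"casg", "casl", "greedy"}:
            raise ValueError(f"unknown method {method!r}")
        self.data = _as_discrete(data, levels, seed)
        self.method = method
        self.ess = ess
        self.moves = tuple(moves)
        self.max_parents = max_parents

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kw) -> "StructureLearner":
        return cls(frame, **kw)

    def fit(self) -> "StructureResults":
        t0 = time.perf_counter()
        if self.method == "greedy":
            res = learning.greedy_search(
                self.data, learning.full_edge_space(self.data.variable_names),
                self.ess, moves=self.moves, max_parents=self.max_parents,
            )
            res.method = "greedy"
        elif self.method == "casg":
            res = learning.cas_g(self.data, self.ess, moves=self.moves,
                                 max_parents=self.max_parents)
        else:
            res = learning.cas_l(self.data, self.ess)
        return StructureResults(
            model=self, learn_result=res, wall_time=time.perf_counter() - t0
        )


@dataclass
class StructureResults:
    model: StructureLearner
    learn_result: learning.LearnResult
    wall_time: float = 0.0

    @property
    def graph(self) -> nx.DiGraph:
        return self.learn_result.graph

    @property
    def score(self) -> float:
        return self.learn_result.score

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def evaluate(self, truth: nx.DiGraph, mode: str = "directed") -> dict:
        """Confusion metrics plus SHD against a gold-standard DAG."""
        rep = metrics(structure_confusion(truth, self.graph, mode))
        rep.shd = shd(truth, self.graph)
        return {
            "precision": rep.precision,
            "recall": rep.recall,
            "accuracy": rep.accuracy,
            "specificity": rep.specificity,
            "f_score": rep.f_score,
            "shd": rep.shd,
        }

    def summary(self) -> pd.DataFrame:
        info = {
            "method": self.learn_result.method,
            "ess": self.model.ess,
            "n_variables": self.model.data.n_variables,
            "n_samples": self.model.data.n_samples,
            "n_edges": self.n_edges,
            "bdeu_score": self.score,
            "edge_space_size": self.learn_result.space_size,
            "iterations": sum(1 for *_, acc in self.learn_result.trace if acc),
            "wall_time_s": round(self.wall_time, 4),
        }
        return pd.DataFrame({"value": pd.Series(info)})
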