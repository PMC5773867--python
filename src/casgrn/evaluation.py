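"""Structure and candidate-set evaluation against gold standards.

Confusion counts are taken over the full pair universe — every ordered
node pair in directed mode, every unordered pair in skeleton mode — so
accuracy and specificity are dominated by true negatives on sparse graphs;
they are reported as defined and interpretation is left to the user.
Undefined ratios (zero denominators) are flagged as NaN, never raised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx

from .cas import CandidateSets

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "structure_confusion",
    "candidate_confusion",
    "metrics",
    "shd",
]


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    mode: str = "directed"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricReport:
    precision: float
    recall: float
    accuracy: float
    specificity: float
    f_score: float
    shd: int | None = None


def _check_nodes(truth: nx.DiGraph, learned: nx.DiGraph) -> list:
    if set(truth.nodes) != set(learned.nodes):
        raise ValueError("graphs must share the same node set")
    return sorted(truth.nodes)


def structure_confusion(
    truth: nx.DiGraph, learned: nx.DiGraph, mode: str = "directed"
) -> ConfusionCounts:
    """Edge-level confusion counts over the full pair universe."""
    nodes = _check_nodes(truth, learned)
    if mode == "directed":
        pairs = [(u, v) for u in nodes for v in nodes if u != v]
        in_truth = lambda u, v: truth.has_edge(u, v)
        in_learned = lambda u, v: learned.has_edge(u, v)
    elif mode == "skeleton":
        pairs = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
        in_truth = lambda u, v: truth.has_edge(u, v) or truth.has_edge(v, u)
        in_learned = lambda u, v: learned.has_edge(u, v) or learned.has_edge(v, u)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    tp = fp = tn = fn = 0
    for u, v in pairs:
        t, l = in_truth(u, v), in_learned(u, v)
        if t and l:
            tp += 1
        elif not t and l:
            fp += 1
        elif t and not l:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp, fp, tn, fn, mode=mode)


def candidate_confusion(
    truth: nx.DiGraph, cands: CandidateSets
) -> tuple[dict[str, ConfusionCounts], float, float]:
    """Per-node candidate-set confusion against true neighborhoods.

    A node's true neighbors are its parents and children in the gold
    standard (undirected adjacency).  Returns per-node counts plus the mean
    over nodes of per-node recall (nodes with no true neighbors are skipped
    in the mean) and the mean candidate-set size.
    """
    nodes = sorted(truth.nodes)
    if set(nodes) != set(cands.candidates):
        raise ValueError("candidate sets and gold standard disagree on nodes")
    per_node: dict[str, ConfusionCounts] = {}
    recalls = []
    sizes = []
    for v in nodes:
        neighbors = set(truth.predecessors(v)) | set(truth.successors(v))
        cset = cands[v]
        others = set(nodes) - {v}
        tp = len(neighbors & cset)
        fn = len(neighbors - cset)
        fp = len(cset - neighbors)
        tn = len(others - neighbors - cset)
        per_node[v] = ConfusionCounts(tp, fp, tn, fn, mode="candidate")
        if neighbors:
            recalls.append(tp / len(neighbors))
        sizes.append(len(cset))
    mean_recall = float(sum(recalls) / len(recalls)) if recalls else math.nan
    mean_size = float(sum(sizes) / len(sizes))
    return per_node, mean_recall, mean_size


def metrics(c: ConfusionCounts) -> MetricReport:
    """Precision, recall, accuracy, specificity, F-score from counts.

    Zero denominators yield NaN (except F-score, which is 0 when
    precision + recall is 0 or either is undefined).
    """
    def ratio(num, den):
        return num / den if den > 0 else math.nan

    precision = ratio(c.tp, c.tp + c.fp)
    recall = ratio(c.tp, c.tp + c.fn)
    accuracy = ratio(c.tp + c.tn, c.total)
    specificity = ratio(c.tn, c.tn + c.fp)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f = 0.0
    else:
        f = 2 * precision * recall / (precision + recall)
    return MetricReport(
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        specificity=specificity,
        f_score=f,
    )


def shd(truth: nx.DiGraph, learned: nx.DiGraph) -> int:
    """Structural Hamming distance with reversal cost 1.

    One edit per unordered pair whose status differs: a missing adjacency
    costs one addition, an extra adjacency one deletion, and a present
    adjacency with the wrong orientation one reversal.
    """
    nodes = _check_nodes(truth, learned)
    dist = 0
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            t_uv, t_vu = truth.has_edge(u, v), truth.has_edge(v, u)
            l_uv, l_vu = learned.has_edge(u, v), learned.has_edge(v, u)
            t_adj, l_adj = t_uv or t_vu, l_uv or l_vu
            if t_adj != l_adj:
                dist += 1
            elif t_adj and (t_uv, t_vu) != (l_uv, l_vu):
                dist += 1
    return dist
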