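"""Input/output and discretization for expression data and benchmark networks.

Expression matrices arrive as delimited text (samples x genes, header row of
gene names).  Benchmark Bayesian networks are read from BIF (Bayesian
Interchange Format), the standard distribution format for networks such as
ALARM and insurance.  Gold-standard structures travel as DREAM-style
tab-separated edge lists (``regulator<TAB>target<TAB>{0,1}``).

Continuous expression values are converted to categories by per-gene 1-D
k-means with deterministic quantile initialization, relabeled so ascending
category index means ascending cluster centroid.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "ExpressionMatrix",
    "DiscreteDataset",
    "read_expression",
    "kmeans_discretize",
    "read_bif",
    "write_bif",
    "read_edge_list",
    "write_edge_list",
]


class FormatError(ValueError):
    """A file violated its declared format."""


@dataclass
class ExpressionMatrix:
    """Real-valued expression matrix, rows = samples, columns = genes."""

    gene_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape[1] != len(self.gene_names):
            raise ValueError(
                f"{len(self.gene_names)} gene names but "
                f"{self.values.shape[1]} columns"
            )
        if self.values.shape[0] < 1 or self.values.shape[1] < 2:
            raise ValueError("need >=1 sample and >=2 genes")
        if np.isnan(self.values).any():
            raise ValueError("missing values present")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class DiscreteDataset:
    """Matrix of category indices with per-variable cardinalities.

    ``data[s, i]`` is the category of variable ``i`` in sample ``s`` and must
    lie in ``[0, cardinalities[i])``.  Degenerate variables (cardinality 1,
    e.g. from a constant expression column) are permitted.
    """

    variable_names: list[str]
    cardinalities: np.ndarray
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.int64)
        self.cardinalities = np.asarray(self.cardinalities, dtype=np.int64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D")
        n_vars = len(self.variable_names)
        if self.data.shape[1] != n_vars or len(self.cardinalities) != n_vars:
            raise ValueError("variable_names, cardinalities and data disagree on width")
        if self.data.shape[0] < 1:
            raise ValueError("need at least one sample")
        if (self.cardinalities < 1).any():
            raise ValueError("cardinalities must be >= 1")
        if (self.data < 0).any() or (self.data >= self.cardinalities[None, :]).any():
            raise ValueError("category index out of range for its cardinality")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_variables(self) -> int:
        return self.data.shape[1]

    def index(self, name: str) -> int:
        try:
            lookup = self._index
        except AttributeError:
            lookup = self._index = {n: i for i, n in enumerate(self.variable_names)}
        return lookup[name]

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self.index(name)]


def read_expression(
    path,
    delimiter: str = "\t",
    transpose: bool = False,
    impute_median: bool = False,
) -> ExpressionMatrix:
    """Read a delimited expression matrix with a header row of gene names.

    Parameters
    ----------
    path : path-like
        Text file; first row gene names, remaining rows numeric.
    delimiter : str
        Field separator (tab by default, ``","`` for CSV).
    transpose : bool
        Set when the file is genes x samples: the header row then names the
        samples (it is discarded) and the first cell of every remaining row
        is the gene name.
    impute_median : bool
        Replace missing cells by their gene's median instead of rejecting
        the file (off by default).
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh if ln.strip()]
    if len(lines) < 2:
        raise FormatError(f"{path}: need a header and at least one data row")
    def parse_cell(cell, lineno, colno, colname):
        if cell == "" or cell.upper() in {"NA", "NAN"}:
            if impute_median:
                return np.nan
            raise FormatError(
                f"{path}: missing value at line {lineno}, column {colno} "
                f"({colname})"
            )
        try:
            return float(cell)
        except ValueError:
            raise FormatError(
                f"{path}: non-numeric cell {cell!r} at line {lineno}, "
                f"column {colno} ({colname})"
            ) from None

    def impute(values):
        for j in range(values.shape[1]):
            col = values[:, j]
            if np.isnan(col).any():
                col[np.isnan(col)] = np.nanmedian(col)
        return values

    if transpose:
        genes, cols = [], []
        for lineno, ln in enumerate(lines[1:], start=2):
            cells = [c.strip() for c in ln.split(delimiter)]
            genes.append(cells[0])
            cols.append([
                parse_cell(cell, lineno, colno, cells[0])
                for colno, cell in enumerate(cells[1:], start=2)
            ])
        if len({len(c) for c in cols}) != 1:
            raise FormatError(f"{path}: ragged rows")
        return ExpressionMatrix(genes, impute(np.asarray(cols, dtype=float).T))
    header = [c.strip() for c in lines[0].split(delimiter)]
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = [c.strip() for c in ln.split(delimiter)]
        if len(cells) != len(header):
            raise FormatError(
                f"{path}: line {lineno} has {len(cells)} fields, expected {len(header)}"
            )
        rows.append([
            parse_cell(cell, lineno, colno + 1, header[colno])
            for colno, cell in enumerate(cells)
        ])
    return ExpressionMatrix(
        gene_names=header, values=impute(np.asarray(rows, dtype=float))
    )


def _lloyd_1d(x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100) -> np.ndarray:
    """1-D k-means with deterministic quantile initialization.

    Centroids start at the ``(i + 0.5)/k`` quantiles, then plain Lloyd
    iterations; the rng only breaks exact centroid ties.  Returns labels
    already relabeled so ascending label = ascending centroid.
    """
    centroids = np.quantile(x, (np.arange(k) + 0.5) / k)
    # collapse coincident initial centroids deterministically
    centroids = np.unique(centroids)
    if len(centroids) < k:
        jitter = rng.normal(0.0, 1e-12, size=k - len(centroids))
        centroids = np.sort(np.concatenate([centroids, centroids[-1] + np.abs(jitter)]))
    for _ in range(max_iter):
        labels = np.argmin(np.abs(x[:, None] - centroids[None, :]), axis=1)
        new = centroids.copy()
        for j in range(k):
            members = x[labels == j]
            if len(members):
                new[j] = members.mean()
        if np.allclose(new, centroids, rtol=0.0, atol=1e-12):
            centroids = new
            break
        centroids = new
    labels = np.argmin(np.abs(x[:, None] - centroids[None, :]), axis=1)
    # drop empty clusters, order by centroid
    used = np.unique(labels)
    order = used[np.argsort(centroids[used], kind="stable")]
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels], dtype=np.int64)


def kmeans_discretize(x: ExpressionMatrix, levels: int = 3, seed: int = 0) -> DiscreteDataset:
    """Discretize each gene column by 1-D k-means into at most ``levels`` bins.

    Category indices are ordered by cluster centroid, so 0 is always the
    lowest-expression bin.  A gene with fewer distinct values than ``levels``
    keeps one category per distinct value; a constant gene collapses to a
    single category (with a warning).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    rng = np.random.default_rng(seed)
    n, p = x.values.shape
    data = np.zeros((n, p), dtype=np.int64)
    cards = np.zeros(p, dtype=np.int64)
    for j in range(p):
        col = x.values[:, j]
        distinct = np.unique(col)
        if len(distinct) == 1:
            warnings.warn(
                f"gene {x.gene_names[j]!r} is constant; single category assigned",
                stacklevel=2,
            )
            data[:, j] = 0
            cards[j] = 1
            continue
        k = min(levels, len(distinct))
        if k == len(distinct):
            # one category per distinct value, already centroid-ordered
            data[:, j] = np.searchsorted(distinct, col)
            cards[j] = k
        else:
            labels = _lloyd_1d(col, k, rng)
            data[:, j] = labels
            cards[j] = labels.max() + 1
    return DiscreteDataset(list(x.gene_names), cards, data)


# ---------------------------------------------------------------------------
# BIF (Bayesian Interchange Format)
# ---------------------------------------------------------------------------

_CPT_ROW_TOL = 1e-6


def _strip_comments(text: str) -> str:
    text = re.sub(r"//[^\n]*", "", text)
    return re.sub(r"/\*.*?\*/", "", text, flags=re.S)


def read_bif(path):
    """Parse a BIF file into a :class:`casgrn.synthetic.BayesianNetwork`.

    Edges follow the probability-block declarations (each conditioning
    variable is a parent of the conditioned one).  CPT rows must sum to 1
    within 1e-6 and are renormalized exactly.
    """
    from .synthetic import BayesianNetwork  # local import avoids a cycle

    with open(path, encoding="utf-8") as fh:
        text = _strip_comments(fh.read())

    states: dict[str, list[str]] = {}
    for m in re.finditer(
        r"variable\s+([\w\-.]+)\s*\{((?:[^{}]|\{[^{}]*\})*)\}", text, flags=re.S
    ):
        if "discrete" not in m.group(2):
            continue
        name, body = m.group(1), m.group(2)
        sm = re.search(r"discrete\s*\[\s*(\d+)\s*\]\s*\{([^}]*)\}", body, flags=re.S)
        if sm is None:
            raise FormatError(f"variable {name}: no discrete state list")
        declared = int(sm.group(1))
        st = [s.strip() for s in sm.group(2).split(",") if s.strip()]
        if len(st) != declared:
            raise FormatError(
                f"variable {name}: declares {declared} states but lists {len(st)}"
            )
        states[name] = st

    dag = nx.DiGraph()
    dag.add_nodes_from(states)
    cpts: dict[str, dict] = {}

    for m in re.finditer(
        r"probability\s*\(\s*([\w\-.]+)\s*(?:\|\s*([\w\-.,\s]+?)\s*)?\)\s*\{(.*?)\}",
        text,
        flags=re.S,
    ):
        child = m.group(1)
        if child not in states:
            raise FormatError(f"probability block for undeclared variable {child!r}")
        parents = tuple(
            p.strip() for p in (m.group(2) or "").split(",") if p.strip()
        )
        for p in parents:
            if p not in states:
                raise FormatError(
                    f"probability block {child}: undeclared parent {p!r}"
                )
        body = m.group(3)
        r = len(states[child])
        parent_cards = [len(states[p]) for p in parents]
        q = int(np.prod(parent_cards)) if parents else 1
        table = np.full((q, r), np.nan)
        if not parents:
            tm = re.search(r"table\s+([^;]+);", body)
            if tm is None:
                raise FormatError(f"probability block {child}: missing table row")
            table[0] = [float(v) for v in tm.group(1).replace(",", " ").split()]
        else:
            for rm in re.finditer(r"\(([^)]*)\)\s*([^;]+);", body):
                cfg = [s.strip() for s in rm.group(1).split(",")]
                if len(cfg) != len(parents):
                    raise FormatError(
                        f"probability block {child}: config {cfg} arity mismatch"
                    )
                idx = []
                for p, s in zip(parents, cfg):
                    if s not in states[p]:
                        raise FormatError(
                            f"probability block {child}: unknown state {s!r} of {p}"
                        )
                    idx.append(states[p].index(s))
                row = int(np.ravel_multi_index(idx, parent_cards)) if parents else 0
                table[row] = [float(v) for v in rm.group(2).replace(",", " ").split()]
        if np.isnan(table).any():
            raise FormatError(f"probability block {child}: incomplete CPT")
        sums = table.sum(axis=1)
        if (np.abs(sums - 1.0) > _CPT_ROW_TOL).any():
            bad = sums[np.abs(sums - 1.0) > _CPT_ROW_TOL][0]
            raise FormatError(
                f"probability block {child}: CPT row sums to {bad:.6g}, not 1"
            )
        table /= sums[:, None]
        cpts[child] = {"parents": parents, "table": table}
        for p in parents:
            dag.add_edge(p, child)

    missing = set(states) - set(cpts)
    if missing:
        raise FormatError(f"missing CPT for variable(s): {sorted(missing)}")

    names = sorted(states)
    return BayesianNetwork(
        dag=dag,
        cardinalities={v: len(states[v]) for v in names},
        cpts=cpts,
        state_names=states,
    )


def write_bif(bn, path) -> None:
    """Serialize a Bayesian network to BIF."""
    lines = ["network unknown {", "}"]
    for v in sorted(bn.cardinalities):
        st = bn.state_names.get(v) or [str(i) for i in range(bn.cardinalities[v])]
        lines.append(f"variable {v} {{")
        lines.append(
            f"  type discrete [ {bn.cardinalities[v]} ] {{ {', '.join(st)} }};"
        )
        lines.append("}")
    for v in sorted(bn.cardinalities):
        cpt = bn.cpts[v]
        parents = cpt["parents"]
        table = cpt["table"]
        if not parents:
            vals = ", ".join(repr(float(x)) for x in table[0])
            lines.append(f"probability ( {v} ) {{")
            lines.append(f"  table {vals};")
        else:
            lines.append(f"probability ( {v} | {', '.join(parents)} ) {{")
            parent_cards = [bn.cardinalities[p] for p in parents]
            for row in range(table.shape[0]):
                idx = np.unravel_index(row, parent_cards)
                cfg = ", ".join(
                    (bn.state_names.get(p) or [str(i) for i in range(bn.cardinalities[p])])[i]
                    for p, i in zip(parents, idx)
                )
                vals = ", ".join(repr(float(x)) for x in table[row])
                lines.append(f"  ({cfg}) {vals};")
        lines.append("}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# DREAM-style edge lists
# ---------------------------------------------------------------------------


def read_edge_list(path, nodes=None) -> nx.DiGraph:
    """Read a 2-3 column tab-separated edge list into a directed graph.

    Rows are ``source<TAB>target<TAB>label`` with label in {0, 1}; only
    label-1 rows become edges, and a missing third column counts as 1.
    ``nodes``, when given, pre-declares the node universe (gold standards
    list absent edges explicitly, but isolated nodes may appear nowhere).
    """
    g = nx.DiGraph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    with open(path, encoding="utf-8") as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) == 1:
                parts = ln.split()
            if len(parts) < 2:
                raise FormatError(f"{path}: line {lineno}: need >=2 columns")
            src, dst = parts[0], parts[1]
            label = parts[2] if len(parts) > 2 else "1"
            if label not in {"0", "1"}:
                raise FormatError(f"{path}: line {lineno}: label {label!r} not in {{0,1}}")
            if src == dst:
                raise FormatError(f"{path}: line {lineno}: self-loop {src!r}")
            g.add_node(src)
            g.add_node(dst)
            if label == "1":
                g.add_edge(src, dst)
    return g


def write_edge_list(path, graph: nx.DiGraph) -> None:
    """Write the graph's edges as ``source<TAB>target<TAB>1`` rows."""
    for u, v in graph.edges():
        if u == v:
            raise ValueError(f"self-loop {u!r} cannot be serialized")
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in sorted(graph.edges()):
            fh.write(f"{u}\t{v}\t1\n")
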