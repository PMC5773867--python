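"""Candidate auto-selection by breakpoint detection in sorted MI vectors.

For each target node the pairwise MIs against all other nodes are sorted
ascending.  Under the null hypothesis the whole vector is one Gaussian
population; under the alternative a single breakpoint k splits it into a
left population of small-sample noise (marginally independent nodes, e.g.
co-parents in a common-effect configuration) and a right population of
genuinely related nodes.  The test statistic is twice the log-likelihood
ratio of the two-segment Gaussian maximum-likelihood fit against the pooled
single-Gaussian fit,

    Q(k) = 2 [ L(x_1..k) + L(x_{k+1}..m) − L(x_1..m) ],

maximized over k.  Nodes ranked above the argmax breakpoint become the
target's candidate neighbors; when no breakpoint is significant (Q ≈ 0
everywhere, e.g. a constant vector) every node is kept — restriction is an
optimization, so the degenerate default is no restriction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets_io import DiscreteDataset
from .mi import MIMatrix, MIRanking, mi_matrix, mi_ranking

__all__ = [
    "SegmentParams",
    "BreakpointResult",
    "CandidateSets",
    "gaussian_segment_loglik",
    "breakpoint_statistic",
    "detect_breakpoint",
    "select_candidates",
    "cas_all",
    "SIGMA_FLOOR",
    "Q_EPSILON",
]

# floor on every fitted segment standard deviation (nats); keeps the
# likelihood finite on (near-)constant segments and makes Q on an exactly
# constant vector identically 0
SIGMA_FLOOR = 1e-4
# numerical gate distinguishing the exact-null case from a real breakpoint
Q_EPSILON = 1e-9

# minimum ranking length that admits a split; below this every node is kept
_MIN_SPLITTABLE = 3


@dataclass
class SegmentParams:
    mu: float
    sigma: float  # floored at SIGMA_FLOOR


@dataclass
class BreakpointResult:
    """Breakpoint position, its statistic, and the fitted segment models.

    ``k`` is 1-based: elements 1..k are the left (unrelated) segment,
    k+1..m the right (related) segment.  ``significant`` is False when the
    best Q does not exceed the numerical epsilon or the vector is too short
    to split, in which case downstream keeps all nodes.
    """

    k: int
    q: float
    left: SegmentParams
    right: SegmentParams
    null_loglik: float
    significant: bool
    m: int = 0


@dataclass
class CandidateSets:
    """Per-node candidate neighbor sets plus breakpoint diagnostics."""

    candidates: dict[str, set[str]]
    breakpoints: dict[str, BreakpointResult] = field(default_factory=dict)

    def __getitem__(self, node: str) -> set[str]:
        return self.candidates[node]

    def allowed_edges(self) -> set[tuple[str, str]]:
        """OR-union edge space: (u, v) allowed iff u ∈ C(v) or v ∈ C(u)."""
        edges: set[tuple[str, str]] = set()
        for v, cset in self.candidates.items():
            for u in cset:
                edges.add((u, v))
                edges.add((v, u))
        return edges


def gaussian_segment_loglik(values) -> tuple[float, SegmentParams]:
    """Gaussian log-likelihood of a segment at its own MLE (mean, biased
    variance), with the variance floored at ``SIGMA_FLOOR**2``."""
    x = np.asarray(values, dtype=float).ravel()
    n = len(x)
    if n < 1:
        raise ValueError("segment must be non-empty")
    mu = float(x.mean())
    var = float(x.var())  # biased (1/n) MLE variance
    var = max(var, SIGMA_FLOOR**2)
    loglik = -0.5 * n * np.log(2.0 * np.pi * var) - float(((x - mu) ** 2).sum()) / (
        2.0 * var
    )
    return float(loglik), SegmentParams(mu=mu, sigma=float(np.sqrt(var)))


def breakpoint_statistic(x, k: int) -> float:
    """Q(k) = 2·[two-segment loglik − pooled loglik] for a split after
    position k (1-based); non-negative up to rounding since the segmented
    MLE dominates the pooled one."""
    x = np.asarray(x, dtype=float).ravel()
    m = len(x)
    if not 1 <= k <= m - 1:
        raise ValueError(f"k={k} out of range [1, {m - 1}]")
    if (np.diff(x) < 0).any():
        raise ValueError("input vector must be sorted ascending")
    l_left, _ = gaussian_segment_loglik(x[:k])
    l_right, _ = gaussian_segment_loglik(x[k:])
    l_null, _ = gaussian_segment_loglik(x)
    return float(2.0 * (l_left + l_right - l_null))


def _seg_loglik_vec(n: np.ndarray, s1: np.ndarray, s2: np.ndarray) -> np.ndarray:
    """Floored-variance Gaussian loglik for segments given size and the
    first two power sums; vectorized over splits."""
    mean = s1 / n
    var = np.maximum(s2 / n - mean**2, SIGMA_FLOOR**2)
    # Σ(x−μ̂)² = n·v̂ evaluated at the floored variance
    vhat = np.maximum(s2 / n - mean**2, 0.0)
    return -0.5 * n * np.log(2.0 * np.pi * var) - n * vhat / (2.0 * var)


def _q_all_splits(x: np.ndarray) -> np.ndarray:
    """Q(k) for k = 1..m−1 in one prefix-sum pass; matches
    :func:`breakpoint_statistic` to rounding."""
    m = len(x)
    x = x - x.mean()  # location shift; Q is location-invariant and this
    # kills the cancellation in the power sums
    c1 = np.cumsum(x)
    c2 = np.cumsum(x * x)
    k = np.arange(1, m, dtype=float)
    left = _seg_loglik_vec(k, c1[:-1], c2[:-1])
    right = _seg_loglik_vec(m - k, c1[-1] - c1[:-1], c2[-1] - c2[:-1])
    null = _seg_loglik_vec(np.array([float(m)]), c1[-1:], c2[-1:])[0]
    return 2.0 * (left + right - null)


def detect_breakpoint(x) -> BreakpointResult:
    """Argmax-of-Q breakpoint search over k ∈ [1, m−1].

    A split at k = m would leave an empty right segment, so the last
    position is excluded; single-point segments are admissible because the
    sigma floor keeps their likelihood finite.  Ties on Q resolve to the
    smallest k (the larger candidate set — false exclusion is the costly
    error for a search-space restriction).  Vectors with m < 3 cannot be
    split meaningfully and return a keep-all result rather than an error.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = len(x)
    if (np.diff(x) < 0).any():
        raise ValueError("input vector must be sorted ascending")
    l_null, pooled = gaussian_segment_loglik(x) if m >= 1 else (0.0, SegmentParams(0, SIGMA_FLOOR))
    if m < _MIN_SPLITTABLE:
        return BreakpointResult(
            k=0, q=0.0, left=pooled, right=pooled, null_loglik=l_null,
            significant=False, m=m,
        )
    # the prefix-sum pass locates the near-argmax region up to ~1e-6
    # rounding noise; the exact two-pass likelihood re-scores that region
    qs = _q_all_splits(x)
    near = np.flatnonzero(qs >= qs.max() - 1e-3) + 1
    exact = {int(k): breakpoint_statistic(x, int(k)) for k in near}
    best_q = max(exact.values())
    # ties (within epsilon) resolve to the smallest k
    best_k = min(k for k, q in exact.items() if q >= best_q - Q_EPSILON)
    best_q = exact[best_k]
    _, left = gaussian_segment_loglik(x[:best_k])
    _, right = gaussian_segment_loglik(x[best_k:])
    return BreakpointResult(
        k=best_k,
        q=float(best_q),
        left=left,
        right=right,
        null_loglik=l_null,
        significant=bool(best_q > Q_EPSILON),
        m=m,
    )


def q_profile(x) -> np.ndarray:
    """Q(k) for every evaluable k, as (k, Q) rows — diagnostics/plotting."""
    x = np.asarray(x, dtype=float).ravel()
    m = len(x)
    if m < _MIN_SPLITTABLE:
        return np.empty((0, 2))
    return np.column_stack([np.arange(1, m), _q_all_splits(x)])


def select_candidates(r: MIRanking) -> tuple[set[str], BreakpointResult]:
    """Candidate neighbors of the ranking's target.

    Nodes ranked strictly above the detected breakpoint (larger MI) are the
    candidates; without a significant breakpoint all m nodes are kept.
    """
    bp = detect_breakpoint(r.values)
    if bp.significant:
        cands = set(r.names[bp.k:])
    else:
        cands = set(r.names)
    cands.discard(r.target)
    return cands, bp


def cas_all(d: DiscreteDataset, m: MIMatrix | None = None) -> CandidateSets:
    """Candidate sets for every node from one shared MI matrix."""
    if d.n_variables < 2:
        raise ValueError("need at least 2 variables")
    if m is None:
        m = mi_matrix(d)
    candidates: dict[str, set[str]] = {}
    breakpoints: dict[str, BreakpointResult] = {}
    for v in m.variable_names:
        cands, bp = select_candidates(mi_ranking(m, v))
        candidates[v] = cands
        breakpoints[v] = bp
    return CandidateSets(candidates=candidates, breakpoints=breakpoints)
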