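"""Plug-in entropy and pairwise mutual information on discrete data.

MI(X, Y) = H(X) + H(Y) − H(X, Y), estimated by maximum-likelihood
(plug-in) entropies of the empirical frequency tables, in nats.  No
small-sample bias correction is applied: the downstream breakpoint model
explicitly treats small-sample MI noise as its null population, so
correcting the bias would change the method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets_io import DiscreteDataset

__all__ = ["entropy", "mutual_information", "mi_matrix", "mi_ranking", "MIMatrix", "MIRanking"]

_MI_UPPER_SLACK = 1e-9


def entropy(counts) -> float:
    """Plug-in entropy −Σ p̂ log p̂ (nats) of a count vector; 0·log 0 ≡ 0."""
    counts = np.asarray(counts, dtype=float).ravel()
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("counts must sum to a positive value")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def mutual_information(x_col, y_col) -> float:
    """MI (nats) between two category vectors via the entropy identity.

    Clamped into [0, min(H(X), H(Y))] to absorb floating-point residue.
    """
    x = np.asarray(x_col, dtype=np.int64)
    y = np.asarray(y_col, dtype=np.int64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 1:
        raise ValueError("need at least one sample")
    rx, ry = int(x.max()) + 1, int(y.max()) + 1
    joint = np.bincount(x * ry + y, minlength=rx * ry).astype(float)
    hx = entropy(joint.reshape(rx, ry).sum(axis=1))
    hy = entropy(joint.reshape(rx, ry).sum(axis=0))
    hxy = entropy(joint)
    return float(np.clip(hx + hy - hxy, 0.0, min(hx, hy) + _MI_UPPER_SLACK))


@dataclass
class MIMatrix:
    """Symmetric matrix of pairwise MI; diagonal holds per-variable entropy."""

    variable_names: list[str]
    values: np.ndarray

    def mi(self, a: str, b: str) -> float:
        i = self.variable_names.index(a)
        j = self.variable_names.index(b)
        return float(self.values[i, j])


@dataclass
class MIRanking:
    """One node's MI against all others, ascending — the vector the
    breakpoint detector scans."""

    target: str
    others: list[tuple[str, float]]

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.others]

    @property
    def values(self) -> np.ndarray:
        return np.array([v for _, v in self.others])

    @property
    def m(self) -> int:
        return len(self.others)


def mi_matrix(d: DiscreteDataset) -> MIMatrix:
    """All n(n−1)/2 pairwise MIs, each computed once; diagonal = entropies."""
    n = d.n_variables
    if n < 2:
        raise ValueError("need at least 2 variables")
    vals = np.zeros((n, n))
    for i in range(n):
        vals[i, i] = entropy(np.bincount(d.data[:, i], minlength=d.cardinalities[i]))
        for j in range(i + 1, n):
            mij = mutual_information(d.data[:, i], d.data[:, j])
            vals[i, j] = mij
            vals[j, i] = mij
    return MIMatrix(list(d.variable_names), vals)


def mi_ranking(m: MIMatrix, target: str) -> MIRanking:
    """Ascending MI ranking of all other variables against ``target``.

    Stable sort; exact MI ties fall back to lexicographic variable order so
    repeated runs are identical.
    """
    if target not in m.variable_names:
        raise ValueError(f"unknown target {target!r}")
    t = m.variable_names.index(target)
    pairs = sorted(
        (
            (name, float(m.values[t, j]))
            for j, name in enumerate(m.variable_names)
            if j != t
        ),
        key=lambda p: (p[1], p[0]),
    )
    return MIRanking(target=target, others=pairs)
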