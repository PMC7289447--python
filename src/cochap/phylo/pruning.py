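"""Felsenstein pruning under the symmetric equal-frequency chain.

The single-column substitution model is the N-state symmetric chain,
normalized to one expected substitution per unit time, with a per-column
rate multiplier r.  Its transition probabilities are closed form:

    P_ii(t) = 1/N + (N-1)/N * exp(-N r t / (N-1))
    P_ij(t) = 1/N -   1/N * exp(-N r t / (N-1))      (i != j)

Because P(t) acts on a vector f as  p_diff * sum(f) + (p_same - p_diff) * f,
pruning never forms a matrix.  Gaps are missing data (partial-likelihood
vector of ones); the root distribution is uniform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .tree import PhyloTree, TreeNode

__all__ = [
    "ColumnModel",
    "symmetric_transition_factors",
    "pruning_loglik_column",
    "ancestral_marginal",
]

GAP = "-"


@dataclass(frozen=True)
class ColumnModel:
    """State set and rate multiplier of one alignment column."""

    states: tuple[str, ...]
    rate: float = 1.0

    def __post_init__(self):
        if len(self.states) < 2:
            raise ValueError("a column model needs at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError("duplicate states")
        if not self.rate > 0:
            raise ValueError("rate must be positive")

    @property
    def n(self) -> int:
        return len(self.states)

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValueError(
                f"state {state!r} outside model state set {self.states}"
            ) from None


def symmetric_transition_factors(n: int, rate: float, t: float) -> tuple[float, float]:
    """Return (P_same, P_diff) of the normalized symmetric chain."""
    e = np.exp(-n * rate * t / (n - 1))
    return 1.0 / n + (n - 1) / n * e, 1.0 / n - e / n


def _leaf_vector(model: ColumnModel, symbol: str) -> np.ndarray:
    if symbol == GAP:
        return np.ones(model.n)
    v = np.zeros(model.n)
    v[model.index(symbol)] = 1.0
    return v


def _upward(tree: PhyloTree, column: Mapping[str, str], model: ColumnModel):
    """Partial likelihoods per node, with a shared log scale factor."""
    partial: dict[TreeNode, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            if node.name not in column:
                raise ValueError(f"leaf {node.name!r} missing from column")
            partial[node] = _leaf_vector(model, column[node.name])
            continue
        f = np.ones(model.n)
        for child in node.children:
            ps, pd = symmetric_transition_factors(model.n, model.rate, child.length)
            fc = partial[child]
            f = f * (pd * fc.sum() + (ps - pd) * fc)
        m = f.max()
        if m > 0:
            f = f / m
            log_scale += np.log(m)
        partial[node] = f
    return partial, log_scale


def pruning_loglik_column(
    tree: PhyloTree, column: Mapping[str, str], model: ColumnModel
) -> float:
    """Log-likelihood of one column; ``-inf`` for impossible data."""
    partial, log_scale = _upward(tree, column, model)
    site = partial[tree.root].mean()  # uniform root distribution
    if site <= 0.0:
        return -np.inf
    return float(np.log(site) + log_scale)


def ancestral_marginal(
    tree: PhyloTree, column: Mapping[str, str], model: ColumnModel
) -> dict[TreeNode, np.ndarray]:
    """Marginal empirical-Bayes posterior state distribution per node.

    The posterior at a node is proportional to (partial likelihood of the
    subtree below) x (likelihood of everything above), the standard
    up-down decomposition.  Returns a node -> probability-vector map over
    ``model.states``; leaves included.
    """
    if all(column.get(name, GAP) == GAP for name in tree.leaf_names):
        warnings.warn("all-gap column: ancestral posteriors are uniform")
        u = np.full(model.n, 1.0 / model.n)
        return {node: u.copy() for node in tree.postorder()}

    partial, _ = _upward(tree, column, model)
    outside: dict[TreeNode, np.ndarray] = {tree.root: np.full(model.n, 1.0 / model.n)}
    for node in tree.preorder():
        g = outside[node]
        for child in node.children:
            sib = g.copy()
            for other in node.children:
                if other is child:
                    continue
                ps, pd = symmetric_transition_factors(
                    model.n, model.rate, other.length
                )
                fo = partial[other]
                sib = sib * (pd * fo.sum() + (ps - pd) * fo)
            ps, pd = symmetric_transition_factors(model.n, model.rate, child.length)
            down = pd * sib.sum() + (ps - pd) * sib  # P symmetric: P^T = P
            m = down.max()
            outside[child] = down / m if m > 0 else down

    posteriors: dict[TreeNode, np.ndarray] = {}
    for node in partial:
        p = partial[node] * outside[node]
        s = p.sum()
        posteriors[node] = p / s if s > 0 else np.full(model.n, 1.0 / model.n)
    return posteriors
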