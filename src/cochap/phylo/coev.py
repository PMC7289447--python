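"""Pairwise Markov substitution model for coevolving column pairs.

Two alignment columns are modelled as a single Markov chain on the product
state space S = A1 x A2 of their residue alphabets.  Only single-position
changes are allowed; a change landing on a pair in the "coevolving
profile" P (the set of favoured residue combinations) has rate s, any
other allowed change has rate d.  The stationary distribution is closed
form,

    pi(x) \\propto (s/d) ** [x in P],

and the chain is reversible with respect to it, which the likelihood
evaluator exploits: the symmetrized generator is diagonalized once per
(s, d) and transition operators are applied as two matrix-vector products
per branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from numba import njit
from scipy.linalg import eigh

from .tree import PhyloTree
from .pruning import GAP

__all__ = ["CoevModel", "coev_rate_matrix", "coev_stationary", "PairPruner", "coev_loglik"]


@dataclass(frozen=True)
class CoevModel:
    """Coevolution model on the product space of two column alphabets."""

    states_a: tuple[str, ...]
    states_b: tuple[str, ...]
    profile: frozenset  # of (a, b) pairs
    s: float
    d: float

    def __post_init__(self):
        if not self.profile:
            raise ValueError("profile must be non-empty")
        space = {(a, b) for a in self.states_a for b in self.states_b}
        if not set(self.profile) <= space:
            raise ValueError("profile must be a subset of the pair state space")
        if not (self.s > 0 and self.d > 0):
            raise ValueError("rates s and d must be positive")

    @property
    def pair_states(self) -> list[tuple[str, str]]:
        return [(a, b) for a in self.states_a for b in self.states_b]

    @property
    def n_states(self) -> int:
        return len(self.states_a) * len(self.states_b)


def _profile_mask(model: CoevModel) -> np.ndarray:
    return np.array([p in model.profile for p in model.pair_states], dtype=bool)


def coev_stationary(model: CoevModel) -> np.ndarray:
    """Closed-form stationary distribution pi \\propto (s/d)^[state in P]."""
    w = np.where(_profile_mask(model), model.s / model.d, 1.0)
    return w / w.sum()


def coev_rate_matrix(model: CoevModel) -> tuple[np.ndarray, np.ndarray]:
    """Dense generator Q (rows sum to zero) and stationary distribution."""
    na, nb = len(model.states_a), len(model.states_b)
    n = na * nb
    mask = _profile_mask(model)
    Q = np.zeros((n, n))
    for ia in range(na):
        for ib in range(nb):
            i = ia * nb + ib
            for ja in range(na):
                if ja != ia:
                    j = ja * nb + ib
                    Q[i, j] = model.s if mask[j] else model.d
            for jb in range(nb):
                if jb != ib:
                    j = ia * nb + jb
                    Q[i, j] = model.s if mask[j] else model.d
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q, coev_stationary(model)


class PairPruner:
    """Pre-compiled pruning engine for one column pair on a fixed tree.

    Restricts the state space to the residues observed in each column
    (gapped leaves are missing data) and caches the single-position move
    structure, so evaluating the log-likelihood at a new (s, d) costs one
    symmetric eigendecomposition plus two matrix-vector products per branch.
    """

    def __init__(
        self,
        tree: PhyloTree,
        column_a: Mapping[str, str],
        column_b: Mapping[str, str],
        profile: Optional[frozenset] = None,
        states_a: Optional[Sequence[str]] = None,
        states_b: Optional[Sequence[str]] = None,
    ):
        leaves = tree.leaf_names
        for name in leaves:
            if name not in column_a or name not in column_b:
                raise ValueError(f"leaf {name!r} missing from column data")
        obs_a = sorted({column_a[l] for l in leaves if column_a[l] != GAP})
        obs_b = sorted({column_b[l] for l in leaves if column_b[l] != GAP})
        if not obs_a or not obs_b:
            raise ValueError("each column needs at least one ungapped leaf")
        if states_a is not None:
            if not set(obs_a) <= set(states_a):
                raise ValueError("observed residues outside supplied states_a")
            obs_a = list(states_a)
        if states_b is not None:
            if not set(obs_b) <= set(states_b):
                raise ValueError("observed residues outside supplied states_b")
            obs_b = list(states_b)
        self.states_a = tuple(obs_a)
        self.states_b = tuple(obs_b)
        self.na, self.nb = len(obs_a), len(obs_b)
        self.n = self.na * self.nb
        idx_a = {a: i for i, a in enumerate(obs_a)}
        idx_b = {b: i for i, b in enumerate(obs_b)}

        observed_pairs = {
            (column_a[l], column_b[l])
            for l in leaves
            if column_a[l] != GAP and column_b[l] != GAP
        }
        if profile is None:
            profile = frozenset(observed_pairs)
        self.profile = frozenset(profile)
        self.n_ungapped = sum(
            1 for l in leaves if column_a[l] != GAP and column_b[l] != GAP
        )

        mask = np.zeros(self.n, dtype=bool)
        for (a, b) in self.profile:
            if a in idx_a and b in idx_b:
                mask[idx_a[a] * self.nb + idx_b[b]] = True
        self._mask = mask

        # single-position move edge lists (structure independent of rates)
        rows, cols = [], []
        for ia in range(self.na):
            for ib in range(self.nb):
                i = ia * self.nb + ib
                for ja in range(self.na):
                    if ja != ia:
                        rows.append(i)
                        cols.append(ja * self.nb + ib)
                for jb in range(self.nb):
                    if jb != ib:
                        rows.append(i)
                        cols.append(ia * self.nb + jb)
        self._rows = np.array(rows, dtype=np.intp)
        self._cols = np.array(cols, dtype=np.intp)
        self._dest_in_profile = mask[self._cols]

        # flattened postorder traversal: node index, parent, branch length,
        # and for leaves the pair-state index (-1 when either column gapped)
        order = list(tree.postorder())
        node_index = {node: i for i, node in enumerate(order)}
        children: list[list[int]] = [[] for _ in order]
        self._lengths = np.array([node.length for node in order])
        self._is_leaf = np.array([node.is_leaf for node in order])
        self._leaf_state = np.full(len(order), -1, dtype=np.int64)
        for node, i in node_index.items():
            for child in node.children:
                children[i].append(node_index[child])
            if node.is_leaf:
                a, b = column_a[node.name], column_b[node.name]
                if a != GAP and b != GAP:
                    self._leaf_state[i] = idx_a[a] * self.nb + idx_b[b]
        self._root = node_index[tree.root]
        if self._is_leaf[self._root]:
            raise ValueError("tree must have at least one internal node")
        # CSR-style child lists for the compiled pruning kernel
        counts = [len(c) for c in children]
        self._child_ptr = np.zeros(len(order) + 1, dtype=np.int64)
        self._child_ptr[1:] = np.cumsum(counts)
        self._child_idx = np.array(
            [c for sub in children for c in sub], dtype=np.int64
        )

    # -- likelihood --------------------------------------------------------
    def operators_for_ratio(self, ratio: float):
        """Diagonalized transition machinery at s/d = ratio, d = 1.

        Because Q(s, d) = d * Q(s/d, 1), the eigenvectors and stationary
        distribution depend on the ratio only; for any d the transition
        operator follows by scaling the eigenvalues with d.  This is what
        makes the ML fit cheap: one eigendecomposition per ratio.
        """
        n = self.n
        rates = np.where(self._dest_in_profile, ratio, 1.0)
        Q = np.zeros((n, n))
        Q[self._rows, self._cols] = rates
        np.fill_diagonal(Q, -Q.sum(axis=1))
        w = np.where(self._mask, ratio, 1.0)
        pi = w / w.sum()
        sq = np.sqrt(pi)
        sym = Q * (sq[:, None] / sq[None, :])
        sym = 0.5 * (sym + sym.T)  # enforce exact symmetry
        lam, V = eigh(sym, check_finite=False)
        U = np.ascontiguousarray(V / sq[:, None])   # D^{-1/2} V
        W = np.ascontiguousarray(V.T * sq[None, :])  # V^T D^{1/2}
        return lam, U, W, pi

    def _operators(self, s: float, d: float):
        lam, U, W, pi = self.operators_for_ratio(s / d)
        return lam * d, U, W, pi

    def loglik_scaled(self, ops, d: float) -> float:
        """Log-likelihood from ratio operators ``ops`` at overall scale d."""
        lam, U, W, pi = ops
        return float(
            _prune_kernel(
                self.n, self._is_leaf, self._leaf_state, self._lengths,
                self._child_ptr, self._child_idx, self._root,
                lam * d, U, W, pi,
            )
        )

    def loglik(self, s: float, d: float) -> float:
        if not (s > 0 and d > 0):
            raise ValueError("rates must be positive")
        lam, U, W, pi = self._operators(s, d)
        if not np.all(np.isfinite(lam)):
            raise FloatingPointError("eigendecomposition of the generator failed")
        return float(
            _prune_kernel(
                self.n, self._is_leaf, self._leaf_state, self._lengths,
                self._child_ptr, self._child_idx, self._root,
                lam, U, W, pi,
            )
        )


@njit(cache=False)
def _prune_kernel(
    n, is_leaf, leaf_state, lengths, child_ptr, child_idx, root,
    lam, U, W, pi,
):
    """Felsenstein pruning in the eigenbasis of the symmetrized generator.

    Internal nodes store both the partial vector f and W @ f so each edge
    costs two matrix-vector products.
    """
    nnodes = lengths.shape[0]
    wpartial = np.zeros((nnodes, n))
    log_scale = 0.0
    ones_w = np.zeros(n)
    for k in range(n):
        acc = 0.0
        for j in range(n):
            acc += W[k, j]
        ones_w[k] = acc
    root_f = np.ones(n)
    for i in range(nnodes):
        if is_leaf[i]:
            continue
        f = np.ones(n)
        for cp in range(child_ptr[i], child_ptr[i + 1]):
            c = child_idx[cp]
            v = np.empty(n)
            if is_leaf[c]:
                st = leaf_state[c]
                if st >= 0:
                    for k in range(n):
                        v[k] = np.exp(lam[k] * lengths[c]) * W[k, st]
                else:
                    for k in range(n):
                        v[k] = np.exp(lam[k] * lengths[c]) * ones_w[k]
            else:
                for k in range(n):
                    v[k] = np.exp(lam[k] * lengths[c]) * wpartial[c, k]
            y = U @ v
            for k in range(n):
                val = y[k]
                if val < 0.0:
                    val = 0.0
                f[k] *= val
        m = 0.0
        for k in range(n):
            if f[k] > m:
                m = f[k]
        if m > 0.0:
            inv = 1.0 / m
            for k in range(n):
                f[k] *= inv
            log_scale += np.log(m)
        if i == root:
            root_f = f
            break
        wpartial[i] = W @ f
    site = 0.0
    for k in range(n):
        site += pi[k] * root_f[k]
    if site <= 0.0:
        return -np.inf
    return np.log(site) + log_scale


def coev_loglik(
    tree: PhyloTree,
    column_a: Mapping[str, str],
    column_b: Mapping[str, str],
    model: CoevModel,
) -> float:
    """Log-likelihood of a column pair under a fully specified CoevModel,
    evaluated on the model's own state space (which must contain the
    observed residues)."""
    pruner = PairPruner(
        tree,
        column_a,
        column_b,
        profile=model.profile,
        states_a=model.states_a,
        states_b=model.states_b,
    )
    return pruner.loglik(model.s, model.d)
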