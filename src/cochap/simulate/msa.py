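"""Sequence simulation on a tree: independent columns and coevolving pairs.

Independent columns evolve under the normalized symmetric 20-state chain
(closed-form transition probabilities, so branches are sampled exactly).
Coevolving column pairs evolve as one Markov chain on the 20x20 pair space
via exact Gillespie simulation along each branch: a single-position change
into a profile pair has rate s, any other single-position change rate d;
the root is drawn from the model's stationary distribution.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .._rng import stream
from ..constants import AMINO_ACIDS
from ..phylo.alignment import Alignment, ColumnInfo
from ..phylo.pruning import symmetric_transition_factors
from ..phylo.tree import PhyloTree

__all__ = [
    "simulate_alignment_independent",
    "simulate_alignment_coev",
    "COMPENSATORY_STATES",
    "COMPENSATORY_PROFILE",
]

_N_AA = len(AMINO_ACIDS)

#: Residues a structurally constrained interface position cycles through
#: in the compensatory-pair scenario: the charged and amide residues whose
#: exchanges preserve an electrostatic/polar interaction.
COMPENSATORY_STATES = "DEKRNQ"

#: Charge/polarity-compensating residue combinations: an acidic residue
#: facing a basic partner (and vice versa), or amide facing amide.  Used
#: as the default coevolving profile of the pair simulator.
COMPENSATORY_PROFILE = frozenset(
    {("D", "K"), ("E", "R"), ("K", "D"), ("R", "E"), ("N", "Q"), ("Q", "N")}
)


def simulate_alignment_independent(
    tree: PhyloTree,
    n_cols: int,
    col_rates: Sequence[float],
    seed: int,
) -> Alignment:
    """Each column evolves independently at its own rate multiplier."""
    if tree.n_leaves == 0:
        raise ValueError("tree has no leaves")
    col_rates = np.asarray(col_rates, dtype=float)
    if len(col_rates) != n_cols:
        raise ValueError("col_rates length must equal n_cols")
    if np.any(col_rates <= 0):
        raise ValueError("column rates must be positive")
    rng = stream(seed, "msa-independent")

    states: dict = {tree.root: rng.integers(_N_AA, size=n_cols)}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent = states[node.parent]
        child = parent.copy()
        for j in range(n_cols):
            ps, _ = symmetric_transition_factors(_N_AA, col_rates[j], node.length)
            if rng.random() >= ps:
                # jump to a uniformly chosen different state
                offset = rng.integers(1, _N_AA)
                child[j] = (parent[j] + offset) % _N_AA
        states[node] = child

    ids, seqs = [], []
    for leaf in tree.leaves:
        ids.append(leaf.name)
        seqs.append("".join(AMINO_ACIDS[i] for i in states[leaf]))
    cols = [ColumnInfo(original_column=j) for j in range(n_cols)]
    return Alignment(ids, seqs, cols)


def simulate_alignment_coev(
    tree: PhyloTree,
    profile: set,
    s: float,
    d: float,
    n_pairs: int,
    seed: int,
    states_a: Sequence[str] = None,
    states_b: Sequence[str] = None,
) -> Alignment:
    """Simulate ``n_pairs`` coevolving column pairs (2*n_pairs columns).

    ``profile`` is a set of (aa, aa) one-letter pairs; ``s`` is the rate of
    any single-position change whose destination pair is in the profile,
    ``d`` the rate of any other single-position change.  ``states_a`` /
    ``states_b`` restrict the per-column alphabets (default: all 20 amino
    acids) — structurally constrained positions, such as the
    charge-compensating interface pairs this emulates, cycle among a few
    compatible residues rather than the full alphabet.  Column ``2k``
    holds position A of pair k and column ``2k+1`` position B.
    """
    if not (s > 0 and d > 0):
        raise ValueError("rates s and d must be positive")
    profile = {(a.upper(), b.upper()) for a, b in profile}
    if n_pairs > 0 and not profile:
        raise ValueError("profile must be non-empty")
    alpha_a = AMINO_ACIDS if states_a is None else "".join(states_a)
    alpha_b = AMINO_ACIDS if states_b is None else "".join(states_b)
    for a, b in profile:
        if a not in alpha_a or b not in alpha_b:
            raise ValueError(f"profile pair {(a, b)!r} outside the state space")
    rng = stream(seed, "msa-coev")

    na, nb = len(alpha_a), len(alpha_b)
    ia = {a: i for i, a in enumerate(alpha_a)}
    ib = {b: i for i, b in enumerate(alpha_b)}
    in_profile = np.zeros((na, nb), dtype=bool)
    for a, b in profile:
        in_profile[ia[a], ib[b]] = True

    ratio = s / d
    w = np.where(in_profile, ratio, 1.0).ravel()
    pi = w / w.sum()

    def evolve_branch(state: tuple[int, int], t: float) -> tuple[int, int]:
        a, b = state
        remaining = t
        while True:
            # rates of the single-position moves out of (a, b)
            dest_a = in_profile[:, b].copy()
            dest_a[a] = False
            dest_b = in_profile[a, :].copy()
            dest_b[b] = False
            n_s = int(dest_a.sum() + dest_b.sum())
            total = n_s * s + ((na - 1) + (nb - 1) - n_s) * d
            wait = rng.exponential(1.0 / total)
            if wait >= remaining:
                return a, b
            remaining -= wait
            rates = np.concatenate(
                [np.where(dest_a, s, d), np.where(dest_b, s, d)]
            )
            rates[a] = 0.0
            rates[na + b] = 0.0
            k = rng.choice(na + nb, p=rates / rates.sum())
            if k < na:
                a = int(k)
            else:
                b = int(k - na)

    leaf_states: dict = {}
    for pair_idx in range(n_pairs):
        root_flat = rng.choice(na * nb, p=pi)
        node_states = {tree.root: (root_flat // nb, root_flat % nb)}
        for node in tree.preorder():
            if node is tree.root:
                continue
            node_states[node] = evolve_branch(node_states[node.parent], node.length)
        for leaf in tree.leaves:
            leaf_states.setdefault(leaf.name, []).append(node_states[leaf])

    ids = [leaf.name for leaf in tree.leaves]
    seqs = []
    for name in ids:
        pairs = leaf_states.get(name, [])
        seqs.append(
            "".join(alpha_a[a] + alpha_b[b] for a, b in pairs)
        )
    cols = []
    for k in range(n_pairs):
        cols.append(ColumnInfo(family="A", original_column=k))
        cols.append(ColumnInfo(family="B", original_column=k))
    return Alignment(ids, seqs, cols)
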