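"""Yule (pure-birth) tree simulation.

Stands in for empirical ortholog-family phylogenies: every lineage splits
at a constant rate, all tips are sampled at the same final time, so the
tree is ultrametric with strictly positive branch lengths.
"""

from __future__ import annotations

from .._rng import stream
from ..phylo.tree import PhyloTree, TreeNode

__all__ = ["generate_yule_tree"]


def generate_yule_tree(n_taxa: int, birth_rate: float, seed: int) -> PhyloTree:
    """Simulate a Yule tree with ``n_taxa`` leaves labelled ``t1..tn``.

    Lineages split at rate ``birth_rate``; after the (n-1)-th split the
    process runs for one further exponential epoch so terminal branches
    are positive.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if not birth_rate > 0:
        raise ValueError("birth_rate must be positive")
    rng = stream(seed, "yule")

    root = TreeNode(length=0.0)
    # active lineages as (node, birth_time)
    active = [(root.add_child(TreeNode()), 0.0), (root.add_child(TreeNode()), 0.0)]
    t = 0.0
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        i = rng.integers(k)
        node, born = active.pop(i)
        node.length = t - born
        active.insert(i, (node.add_child(TreeNode()), t))
        active.insert(i + 1, (node.add_child(TreeNode()), t))
    t += rng.exponential(1.0 / (len(active) * birth_rate))
    for label, (node, born) in enumerate(active, start=1):
        node.name = f"t{label}"
        node.length = t - born
    return PhyloTree(root)
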