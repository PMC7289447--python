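"""Rooted phylogenetic trees with branch lengths.

Branch lengths are in expected substitutions per site.  The tree is the
fixed input to all likelihood computations: topology and lengths are never
re-estimated here.  Newick parsing is delegated to dendropy; writing uses a
deterministic recursive serializer so identical trees always produce
identical text.
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy

__all__ = ["TreeNode", "PhyloTree", "read_newick", "write_newick"]


class TreeNode:
    """Node of a rooted tree; ``length`` is the branch to the parent."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.name or ''} {kind} length={self.length}>"


class PhyloTree:
    """Rooted tree with unique leaf labels and non-negative branch lengths."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        names = self.leaf_names
        if len(names) != len(set(names)):
            raise ValueError("leaf labels must be unique")
        for node in self.postorder():
            if not (node.length >= 0.0) or node.length != node.length:
                raise ValueError(
                    f"branch length of node {node.name!r} must be finite and >= 0"
                )

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        """Children before parents (iterative, so deep trees are fine)."""
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    # -- Newick ------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str, default_length: Optional[float] = None) -> "PhyloTree":
        """Parse a Newick string.

        ``default_length`` substitutes for missing branch lengths; if None
        (the default) a missing length on a non-root edge is an error.
        """
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as exc:  # dendropy raises several error types
            raise ValueError(f"Newick parse error: {exc}") from exc

        def convert(dnode, is_root: bool) -> TreeNode:
            length = dnode.edge.length
            if length is None:
                if is_root:
                    length = 0.0
                elif default_length is not None:
                    length = default_length
                else:
                    raise ValueError(
                        "missing branch length (pass default_length to allow)"
                    )
            label = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = TreeNode(name=label, length=length)
            for child in dnode.child_nodes():
                node.add_child(convert(child, False))
            return node

        return cls(convert(dtree.seed_node, True))

    def to_newick(self) -> str:
        def serialize(node: TreeNode) -> str:
            if node.is_leaf:
                body = node.name or ""
            else:
                body = "(" + ",".join(serialize(c) for c in node.children) + ")"
                if node.name:
                    body += node.name
            if node.parent is not None:
                body += f":{node.length:.12g}"
            return body

        return serialize(self.root) + ";"

    def copy(self) -> "PhyloTree":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree n_leaves={self.n_leaves} total_length={self.total_length:.4g}>"


def read_newick(path, default_length: Optional[float] = None) -> PhyloTree:
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read(), default_length=default_length)


def write_newick(tree: PhyloTree, path=None) -> str:
    """Serialize ``tree``; if ``path`` is given also write it there."""
    text = tree.to_newick() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
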