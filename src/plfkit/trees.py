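"""Rooted phylogenetic trees with node ages and branch lengths.

A minimal mutable tree used by the likelihood kernel and the MCMC search.
Clock-constrained (ultrametric) trees carry node ages; branch lengths are
derived as ``parent.age - node.age``. Arbitrary rooted trees read from
newick carry explicit branch lengths and may leave ages unset.
"""

from __future__ import annotations

from typing import Iterator, Optional

import dendropy


class Node:
    __slots__ = ("label", "age", "length", "parent", "children")

    def __init__(self, label: Optional[str] = None, age: Optional[float] = None,
                 length: Optional[float] = None):
        self.label = label
        self.age = age
        self.length = length  # edge length to parent
        self.parent: Optional[Node] = None
        self.children: list[Node] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def left(self) -> "Node":
        return self.children[0]

    @property
    def right(self) -> "Node":
        return self.children[1]

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, age={self.age}, length={self.length})"


class Tree:
    """A rooted tree. Binary except for multifurcating consensus summaries."""

    def __init__(self, root: Node):
        self.root = root

    # ---- traversal ----------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                yield node
            else:
                stack.append((node, True))
                for c in reversed(node.children):
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.postorder() if not n.is_leaf]

    def taxa(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_taxa(self) -> int:
        return len(self.leaves())

    # ---- clock bookkeeping --------------------------------------------
    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.internal_nodes())

    def set_lengths_from_ages(self) -> None:
        for n in self.postorder():
            if n.parent is not None:
                n.length = n.parent.age - n.age

    def set_ages_from_lengths(self) -> None:
        """Assign ages from root-to-node depths; requires an ultrametric tree."""
        depth = {self.root: 0.0}
        for n in self.preorder():
            if n.parent is not None:
                depth[n] = depth[n.parent] + (n.length or 0.0)
        height = max(depth[l] for l in self.leaves())
        for n in self.postorder():
            n.age = height - depth[n]

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = []
        depth = {self.root: 0.0}
        for n in self.preorder():
            if n.parent is not None:
                depth[n] = depth[n.parent] + (n.length or 0.0)
            if n.is_leaf:
                depths.append(depth[n])
        return max(depths) - min(depths) <= tol * max(1.0, max(depths))

    # ---- copying -------------------------------------------------------
    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            c = Node(node.label, node.age, node.length)
            for ch in node.children:
                c.add_child(clone(ch))
            return c

        return Tree(clone(self.root))

    # ---- newick --------------------------------------------------------
    def to_newick(self, include_lengths: bool = True, label_internal: bool = False,
                  precision: int = 12) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.label or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if label_internal and node.label:
                    s += str(node.label)
            if include_lengths and node.parent is not None and node.length is not None:
                s += f":{node.length:.{precision}g}"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "Tree":
        dt = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dt)

    @classmethod
    def from_dendropy(cls, dt: "dendropy.Tree") -> "Tree":
        def conv(dn) -> Node:
            label = dn.taxon.label if dn.taxon is not None else dn.label
            n = Node(label=label, length=dn.edge.length)
            for c in dn.child_nodes():
                n.add_child(conv(c))
            return n

        return cls(conv(dt.seed_node))

    def to_dendropy(self, taxon_namespace=None) -> "dendropy.Tree":
        return dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 taxon_namespace=taxon_namespace)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tree({self.n_taxa} taxa)"


def read_trees(path) -> list[Tree]:
    """Read a newick file possibly containing several trees."""
    tl = dendropy.TreeList.get(path=str(path), schema="newick")
    return [Tree.from_dendropy(t) for t in tl]
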