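"""Phylogenetic tree container with Newick round-tripping.

A tree node carries either a branch length (substitutions/site, toward its
parent) or a node age.  Ages are stored in Ma and must strictly decrease
from root to tips.  Newick parsing is delegated to dendropy; writing is a
direct serialization that preserves branch lengths to 10 significant
digits.
"""

from __future__ import annotations

import dendropy


class Node:
    __slots__ = ("name", "children", "parent", "length", "age")

    def __init__(self, name=None, length=None, age=None):
        self.name = name
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.age = age

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, tips={len(self.tip_set())})"

    def tip_set(self) -> frozenset[str]:
        return frozenset(n.name for n in postorder(self) if n.is_tip)


def postorder(node: Node):
    for child in node.children:
        yield from postorder(child)
    yield node


def preorder(node: Node):
    yield node
    for child in node.children:
        yield from preorder(child)


class PhyloTree:
    """Rooted (or root-trifurcating, i.e. unrooted) tree."""

    def __init__(self, root: Node):
        self.root = root
        names = self.tip_names()
        if len(set(names)) != len(names):
            raise ValueError("duplicate tip labels")

    # -- topology access -------------------------------------------------
    def postorder(self):
        return postorder(self.root)

    def preorder(self):
        return preorder(self.root)

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    @property
    def is_rooted(self) -> bool:
        return len(self.root.children) == 2

    def find_clade(self, tip_labels) -> Node:
        """Most recent common ancestor node spanning exactly ``tip_labels``."""
        want = frozenset(tip_labels)
        for node in self.postorder():
            if node.tip_set() == want:
                return node
        raise KeyError(f"no clade with tips {sorted(want)}")

    def mrca(self, tip_labels) -> Node:
        want = set(tip_labels)
        for node in self.postorder():
            if want <= node.tip_set():
                return node
        raise KeyError(f"tips {sorted(want)} not all present")

    def copy(self) -> "PhyloTree":
        def rec(node: Node) -> Node:
            new = Node(node.name, node.length, node.age)
            for c in node.children:
                new.add_child(rec(c))
            return new

        return PhyloTree(rec(self.root))

    # -- ages <-> branch lengths -----------------------------------------
    def validate_ages(self) -> None:
        for node in self.postorder():
            if node.is_tip:
                continue
            if node.age is None:
                raise ValueError(f"internal node {node.name!r} lacks an age")
            for c in node.children:
                child_age = c.age if c.age is not None else 0.0
                if not node.age > child_age:
                    raise ValueError(
                        f"age of {node.name!r} ({node.age}) not greater than "
                        f"child {c.name!r} ({child_age})"
                    )

    def branch_durations(self) -> dict[Node, float]:
        """Parent age minus node age (tips count as age 0), same units as ages."""
        self.validate_ages()
        out = {}
        for node in self.postorder():
            if node.parent is None:
                continue
            age = node.age if node.age is not None else 0.0
            out[node] = node.parent.age - age
        return out

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({len(self.tip_names())} tips)"


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string (topology, labels, branch lengths)."""
    dtree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=False
    )

    def rec(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label, length=dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(rec(dchild))
        return node

    return PhyloTree(rec(dtree.seed_node))


def write_newick(tree: PhyloTree, include_lengths: bool = True) -> str:
    def fmt(node: Node) -> str:
        if node.is_tip:
            s = node.name or ""
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                s += node.name
        if include_lengths and node.length is not None and node.parent is not None:
            s += f":{node.length:.10g}"
        return s

    return fmt(tree.root) + ";"


def timetree_to_newick(tree: PhyloTree) -> str:
    """Serialize an age-annotated tree using parent-child age differences."""
    tree.validate_ages()

    def fmt(node: Node) -> str:
        if node.is_tip:
            s = node.name or ""
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name:
                s += node.name
        if node.parent is not None:
            age = node.age if node.age is not None else 0.0
            s += f":{node.parent.age - age:.10g}"
        return s

    return fmt(tree.root) + ";"
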