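"""Lightweight rooted/unrooted tree container with Newick I/O.

Newick parsing and serialisation are delegated to :mod:`dendropy`; the
internal structure is a plain parent/children node graph that the
likelihood, placement and reconciliation machinery manipulate directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

_NEWICK_META = set("()[]{}/\\,;:=*'\"`<>! \t\n")


class NewickError(ValueError):
    pass


@dataclass
class Node:
    label: str | None = None
    length: float | None = None
    support: float | None = None
    children: list["Node"] = field(default_factory=list)
    parent: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child


class Tree:
    """Rooted tree (an unrooted tree is represented by its arbitrary rooting,
    with ``rooted=False``)."""

    def __init__(self, root: Node, rooted: bool = True):
        self.root = root
        self.rooted = rooted
        labels = [n.label for n in self.leaves()]
        if len(set(labels)) != len(labels):
            raise NewickError("duplicate leaf labels")
        for node in self.postorder():
            if node.length is not None and node.length < 0:
                raise NewickError(f"negative branch length at {node.label or 'internal node'}")

    # -- traversal ---------------------------------------------------------
    def postorder(self):
        out = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out[::-1]

    def preorder(self):
        return list(reversed(self.postorder()))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find_leaf(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise KeyError(label)

    # -- structure ---------------------------------------------------------
    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            for c in node.children:
                new.add_child(clone(c))
            return new

        return Tree(clone(self.root), self.rooted)

    def prune_taxa(self, labels) -> "Tree":
        """Remove the given leaves, suppressing unifurcations (lengths add)."""
        labels = set(labels)
        tree = self.copy()

        def prune(node: Node) -> Node | None:
            if node.is_leaf:
                return None if node.label in labels else node
            kept = [prune(c) for c in node.children]
            kept = [c for c in kept if c is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if node.length is not None and child.length is not None:
                    child.length = child.length + node.length
                elif node.length is not None:
                    child.length = node.length
                child.parent = None
                return child
            node.children = []
            for c in kept:
                node.add_child(c)
            return node

        root = prune(tree.root)
        if root is None:
            raise ValueError("pruning removed every leaf")
        return Tree(root, self.rooted)

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each as the smaller-or-lexical side."""
        all_leaves = frozenset(self.leaf_labels())
        out = set()
        for node in self.postorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(n.label for n in _subtree_leaves(node))
            other = all_leaves - side
            if len(side) < 2 or len(other) < 2:
                continue
            out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
        return out

    def __eq__(self, other):
        if not isinstance(other, Tree):
            return NotImplemented
        return (set(self.leaf_labels()) == set(other.leaf_labels())
                and self.bipartitions() == other.bipartitions())

    def __hash__(self):
        return hash(frozenset(self.bipartitions()))


def _subtree_leaves(node: Node):
    stack, out = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


# -- Newick I/O ------------------------------------------------------------

def _from_dendropy(dnode) -> Node:
    label = None
    if dnode.taxon is not None:
        label = dnode.taxon.label
    elif dnode.label:
        label = dnode.label
    node = Node(label=label, length=dnode.edge.length)
    for child in dnode.child_nodes():
        node.add_child(_from_dendropy(child))
    return node


def parse_newick(text: str, rooted: bool = True) -> Tree:
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickError(f"Newick parse error: {exc}") from exc
    return Tree(_from_dendropy(dtree.seed_node), rooted=rooted)


def read_newick(path, rooted: bool = True) -> Tree:
    with open(path) as fh:
        return parse_newick(fh.read(), rooted=rooted)


def _quote_label(label: str) -> str:
    if any(c in _NEWICK_META for c in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_node(node: Node) -> str:
    if node.is_leaf:
        out = _quote_label(node.label or "")
    else:
        out = "(" + ",".join(_format_node(c) for c in node.children) + ")"
        if node.support is not None:
            out += format(node.support, "g")
        elif node.label:
            out += _quote_label(node.label)
    if node.length is not None:
        out += ":" + format(node.length, ".10g")
    return out


def write_newick(tree: Tree, path=None) -> str:
    """Serialise; branch lengths kept to 10 significant digits."""
    text = _format_node(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text
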