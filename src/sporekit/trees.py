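"""Minimal phylogenetic tree container with the operations the window
scanner needs: newick round-trip, outgroup rooting and clade enumeration.

Unrooted trees are represented with a trifurcating root node; rooting
inserts a bifurcating root on a chosen edge and re-hangs the tree.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator

log = logging.getLogger(__name__)


class Node:
    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.support: float | None = None
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self) -> Iterator["Node"]:
        """Preorder traversal."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list["Node"]:
        return [n for n in self.walk() if n.is_leaf]

    def leaf_names(self) -> frozenset[str]:
        return frozenset(n.name for n in self.leaves())


class PhyloTree:
    """Leaf-labelled tree with branch lengths; ``rooted`` marks whether the
    root is a true bifurcating root or a conventional trifurcation."""

    def __init__(self, root: Node, rooted: bool = False):
        self.root = root
        self.rooted = rooted
        names = [n.name for n in root.leaves()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate leaf labels")

    # -- basic accessors ---------------------------------------------------
    def leaf_names(self) -> frozenset[str]:
        return self.root.leaf_names()

    def clades(self, min_size: int = 1) -> list[frozenset[str]]:
        """Leaf sets of all internal nodes below the root (plus singletons
        when min_size == 1); the root's full leaf set is excluded."""
        out = []
        for node in self.root.walk():
            if node is self.root:
                continue
            ls = node.leaf_names()
            if len(ls) >= min_size:
                out.append(ls)
        return out

    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.support = node.support
            for c in node.children:
                new.add(clone(c))
            return new

        return PhyloTree(clone(self.root), self.rooted)

    # -- distances ---------------------------------------------------------
    def path_distances(self) -> dict[tuple[str, str], float]:
        """Patristic distances between all leaf pairs (oracle helper)."""
        dists: dict[tuple[str, str], float] = {}

        def collect(node: Node) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            below: list[dict[str, float]] = []
            for child in node.children:
                d = collect(child)
                below.append({k: v + child.length for k, v in d.items()})
            merged: dict[str, float] = {}
            for i, di in enumerate(below):
                for j in range(i + 1, len(below)):
                    for a, da in di.items():
                        for b, db in below[j].items():
                            key = (a, b) if a < b else (b, a)
                            dists[key] = da + db
                merged.update(di)
            return merged

        collect(self.root)
        return dists

    # -- newick ------------------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            sup = "" if node.support is None else f"{node.support:.4g}"
            return f"({inner}){sup}:{node.length:.10g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    @classmethod
    def from_newick(cls, text: str, rooted: bool | None = None) -> "PhyloTree":
        tokens = _tokenize(text.strip().rstrip(";"))
        pos = [0]

        def parse() -> Node:
            node = Node()
            if tokens[pos[0]] == "(":
                pos[0] += 1
                node.add(parse())
                while tokens[pos[0]] == ",":
                    pos[0] += 1
                    node.add(parse())
                assert tokens[pos[0]] == ")", "unbalanced newick"
                pos[0] += 1
            if pos[0] < len(tokens) and tokens[pos[0]] not in "(),:":
                label = tokens[pos[0]]
                pos[0] += 1
                if node.is_leaf:
                    node.name = label
                else:
                    try:
                        node.support = float(label)
                    except ValueError:
                        node.name = label
            if pos[0] < len(tokens) and tokens[pos[0]] == ":":
                node.length = float(tokens[pos[0] + 1])
                pos[0] += 2
            return node

        root = parse()
        if rooted is None:
            rooted = len(root.children) == 2
        return cls(root, rooted)


def _tokenize(text: str) -> list[str]:
    tokens, buf = [], []
    for ch in text:
        if ch in "(),:":
            if buf:
                tokens.append("".join(buf))
                buf = []
            tokens.append(ch)
        elif not ch.isspace():
            buf.append(ch)
    if buf:
        tokens.append("".join(buf))
    return tokens


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def root_tree(tree: PhyloTree, outgroup: Iterable[str]) -> PhyloTree:
    """Root an unrooted tree on its outgroup.

    If the outgroup forms a clade (a split of the unrooted tree), the root
    is placed at the midpoint of that stem edge. Otherwise the tree is
    rooted on the terminal edge of the first outgroup id, deterministically,
    with a warning: monophyly calls are then still well defined but the
    outgroup placement itself is unreliable in that window.
    """
    out = frozenset(outgroup)
    tree = tree.copy()
    all_leaves = tree.leaf_names()
    missing = out - all_leaves
    if missing:
        raise KeyError(f"outgroup ids not in tree: {sorted(missing)}")

    stem: Node | None = None
    for node in tree.root.walk():
        if node is tree.root:
            continue
        ls = node.leaf_names()
        if ls == out or all_leaves - ls == out:
            stem = node
            break
    if stem is None:
        first = sorted(out)[0]
        stem = next(n for n in tree.root.walk() if n.name == first)
        log.warning("outgroup not monophyletic; rooting on terminal edge of %s", first)

    return _root_on_edge(tree, stem)


def _root_on_edge(tree: PhyloTree, child: Node) -> PhyloTree:
    """Re-root ``tree`` at the midpoint of the edge above ``child``."""
    half = child.length / 2.0
    parent = child.parent
    assert parent is not None
    parent.children.remove(child)

    # reverse the edges on the path from the old parent up to the old root
    path: list[Node] = []
    n: Node | None = parent
    while n is not None:
        path.append(n)
        n = n.parent
    edge_lengths = [p.length for p in path]  # length of path[i] -> its parent
    for lower, upper in zip(path, path[1:]):
        upper.children.remove(lower)
    for i, (lower, upper) in enumerate(zip(path, path[1:])):
        upper.parent = None
        lower.add(upper)
        upper.length = edge_lengths[i]

    new_root = Node()
    child.parent = None
    child.length = half
    parent.parent = None
    parent.length = half
    new_root.add(child)
    new_root.add(parent)
    # splice out any node left with a single child (e.g. the old root)
    _suppress_unifurcations(new_root)
    return PhyloTree(new_root, rooted=True)


def _suppress_unifurcations(root: Node) -> None:
    for node in list(root.walk()):
        while len(node.children) == 1 and node is not root:
            only = node.children[0]
            only.length += node.length
            up = node.parent
            assert up is not None
            idx = up.children.index(node)
            up.children[idx] = only
            only.parent = up
            node = only
    # a root child that is an internal unifurcation
    for child in list(root.children):
        if len(child.children) == 1:
            only = child.children[0]
            only.length += child.length
            only.parent = root
            root.children[root.children.index(child)] = only
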