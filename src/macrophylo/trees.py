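"""Rooted-tree container and topological utilities.

Everything downstream (supertree search, support scoring, shift detection,
ghost-range inference) manipulates rooted trees whose leaves are taxon
labels — typically valid family names.  This module provides a deliberately
small tree class plus the topological primitives those stages need: clade
extraction, pruning, polytomy resolution, NNI/SPR neighbourhoods and
exhaustive enumeration of small topologies.  File parsing is delegated to
dendropy; only newick writing is done by hand (the output is simple enough
that round-tripping through a third structure buys nothing).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy

__all__ = [
    "Node",
    "Tree",
    "TreeParseError",
    "UnrootedTreeError",
    "parse_tree_files",
    "parse_newick",
    "all_rooted_topologies",
    "n_rooted_topologies",
    "rf_distance",
    "random_bifurcating_tree",
]


class TreeParseError(ValueError):
    """A tree file could not be parsed as the requested format."""


class UnrootedTreeError(ValueError):
    """A tree explicitly flagged as unrooted was supplied where a rooted
    interpretation is required."""


class Node:
    """A node of a rooted tree: leaves carry a label, internals carry children.

    ``age`` is an optional node age in Ma before present (used by the
    synthetic birth–death generator; analysis stages ignore it).
    """

    __slots__ = ("children", "label", "age")

    def __init__(self, label: str | None = None,
                 children: list["Node"] | None = None,
                 age: float | None = None):
        self.label = label
        self.children = children if children is not None else []
        self.age = age

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "Node":
        if self.is_leaf:
            return Node(self.label, None, self.age)
        return Node(self.label, [c.copy() for c in self.children], self.age)


class Tree:
    """A rooted tree with uniquely labelled leaves."""

    def __init__(self, root: Node, tree_id: str | None = None):
        self.root = root
        self.tree_id = tree_id

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, tree_id: str | None = None) -> "Tree":
        return parse_newick(newick, tree_id=tree_id)

    @classmethod
    def from_nested(cls, nested, tree_id: str | None = None) -> "Tree":
        """Build from nested tuples/strings, e.g. ``(("A", "B"), "C")``."""

        def build(x) -> Node:
            if isinstance(x, str):
                return Node(label=x)
            return Node(children=[build(c) for c in x])

        return cls(build(nested), tree_id=tree_id)

    def copy(self) -> "Tree":
        return Tree(self.root.copy(), tree_id=self.tree_id)

    # -- traversal and basic queries ----------------------------------

    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def leaf_set(self) -> frozenset[str]:
        return frozenset(self.leaf_labels)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def is_bifurcating(self) -> bool:
        return all(n.is_leaf or len(n.children) == 2 for n in self.postorder())

    def validate(self) -> None:
        labels = self.leaf_labels
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate leaf labels: {dupes}")

    # -- clades --------------------------------------------------------

    def clades(self, include_leaves: bool = False,
               include_root: bool = True) -> set[frozenset[str]]:
        """Clades as frozensets of leaf labels.

        By default returns internal-node clades including the root (full
        leaf set).  Trivial single-leaf clades are excluded unless asked for.
        """
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                cl = frozenset([node.label])
            else:
                cl = frozenset().union(*(below[id(c)] for c in node.children))
            below[id(node)] = cl
            if node.is_leaf and not include_leaves:
                continue
            out.add(cl)
        if not include_root:
            out.discard(self.leaf_set)
        return out

    def clade_map(self) -> dict[int, frozenset[str]]:
        """Map ``id(node)`` -> leaf-label set below that node."""
        below: dict[int, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[id(node)] = frozenset([node.label])
            else:
                below[id(node)] = frozenset().union(
                    *(below[id(c)] for c in node.children))
        return below

    def parent_map(self) -> dict[int, Node | None]:
        parents: dict[int, Node | None] = {id(self.root): None}
        for node in self.postorder():
            for c in node.children:
                parents[id(c)] = node
        return parents

    def mrca(self, labels: Iterable[str]) -> Node:
        want = frozenset(labels)
        missing = want - self.leaf_set
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        below = self.clade_map()
        best: Node | None = None
        for node in self.postorder():
            if want <= below[id(node)]:
                if best is None or len(below[id(node)]) < len(below[id(best)]):
                    best = node
        assert best is not None
        return best

    # -- editing -------------------------------------------------------

    def remove_leaves(self, labels: Iterable[str]) -> "Tree":
        """Return a copy with the given leaves deleted and degree-2 nodes
        suppressed.  May return a tree with a single leaf (caller decides
        whether that is acceptable)."""
        drop = set(labels)

        def rebuild(node: Node) -> Node | None:
            if node.is_leaf:
                return None if node.label in drop else Node(node.label, None,
                                                            node.age)
            kids = [k for k in (rebuild(c) for c in node.children)
                    if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return Node(node.label, kids, node.age)

        new_root = rebuild(self.root)
        if new_root is None:
            raise ValueError("all leaves removed")
        return Tree(new_root, tree_id=self.tree_id)

    def restrict_to(self, labels: Iterable[str]) -> "Tree":
        keep = set(labels)
        return self.remove_leaves(set(self.leaf_labels) - keep)

    def resolve_polytomies(self, rng) -> "Tree":
        """Return a bifurcating copy; multifurcations are resolved by
        repeatedly pairing two children chosen by ``rng`` (deterministic
        for a seeded generator)."""
        t = self.copy()
        for node in t.postorder():
            while len(node.children) > 2:
                i, j = sorted(rng.choice(len(node.children), size=2,
                                         replace=False))
                a = node.children[i]
                b = node.children[j]
                merged = Node(children=[a, b])
                node.children = ([c for k, c in enumerate(node.children)
                                  if k not in (i, j)] + [merged])
        return t

    # -- output --------------------------------------------------------

    def to_newick(self, node_labels: dict[frozenset[str], str] | None = None,
                  include_ages: bool = False) -> str:
        below = self.clade_map() if node_labels else None

        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                lbl = ""
                if node_labels is not None:
                    lbl = node_labels.get(below[id(node)], "")
                s = f"({inner}){lbl}"
            if include_ages and node.age is not None:
                s += f":{node.age:g}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.to_newick()!r})"


# ---------------------------------------------------------------------------
# parsing


def _from_dendropy(dtree: "dendropy.Tree", tree_id: str | None) -> Tree:
    if dtree.is_rooted is False:
        raise UnrootedTreeError(
            f"tree {tree_id or '<anonymous>'} is explicitly unrooted; "
            "supply rooted trees ([&R] or unannotated newick)")

    def conv(dnode) -> Node:
        if dnode.is_leaf():
            return Node(label=dnode.taxon.label.replace(" ", "_"))
        return Node(children=[conv(c) for c in dnode.child_nodes()])

    tree = Tree(conv(dtree.seed_node), tree_id=tree_id)
    tree.validate()
    return tree


def parse_newick(newick: str, tree_id: str | None = None) -> Tree:
    try:
        dtree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise TreeParseError(f"malformed newick: {exc}") from exc
    return _from_dendropy(dtree, tree_id)


def parse_tree_files(paths: Sequence[str | Path],
                     schema: str = "newick") -> list[Tree]:
    """Parse one or more newick/NEXUS files into a list of rooted trees.

    Tree ids are ``<filename>#<k>`` for the k-th tree of each file.
    Malformed files raise :class:`TreeParseError` naming the file;
    explicitly unrooted trees raise :class:`UnrootedTreeError`.
    """
    if schema not in ("newick", "nexus"):
        raise ValueError(f"unsupported schema {schema!r}")
    trees: list[Tree] = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        try:
            tl = dendropy.TreeList.get(path=str(path), schema=schema)
        except Exception as exc:
            raise TreeParseError(f"{path}: {exc}") from exc
        for k, dtree in enumerate(tl, start=1):
            trees.append(_from_dendropy(dtree, f"{path.name}#{k}"))
    return trees


# ---------------------------------------------------------------------------
# enumeration, random trees, distances


def n_rooted_topologies(n: int) -> int:
    """(2n-3)!! — the number of rooted bifurcating topologies on n leaves."""
    out = 1
    for k in range(3, 2 * n - 2, 2):
        out *= k
    return out


def all_rooted_topologies(labels: Sequence[str]) -> Iterator[Tree]:
    """Yield every rooted bifurcating topology on the given leaves.

    Uses stepwise addition: each successive leaf is attached on every edge
    (including the root edge) of every partial topology.  Counts follow the
    double factorial, so keep n small (n=8 is already 135 135 trees).
    """
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")

    def attach_everywhere(tree: Node, leaf: str) -> Iterator[Node]:
        # new root above the old one
        yield Node(children=[tree.copy(), Node(label=leaf)])

        def recurse(node: Node, path: list[int]) -> Iterator[list[int]]:
            for i, child in enumerate(node.children):
                yield path + [i]
                if not child.is_leaf:
                    yield from recurse(child, path + [i])

        for path in recurse(tree, []):
            new = tree.copy()
            node = new
            for i in path[:-1]:
                node = node.children[i]
            i = path[-1]
            node.children[i] = Node(children=[node.children[i],
                                              Node(label=leaf)])
            yield new

    partial: list[Node] = [Node(children=[Node(label=labels[0]),
                                          Node(label=labels[1])])]
    for leaf in labels[2:]:
        partial = [t for p in partial for t in attach_everywhere(p, leaf)]
    for p in partial:
        yield Tree(p)


def random_bifurcating_tree(labels: Sequence[str], rng) -> Tree:
    """Uniform-ish random rooted bifurcating topology by random sequential
    addition (each leaf attached on an edge chosen uniformly)."""
    labels = list(labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 labels")
    order = list(rng.permutation(len(labels)))
    root = Node(children=[Node(label=labels[order[0]]),
                          Node(label=labels[order[1]])])
    tree = Tree(root)
    for idx in order[2:]:
        tree = _attach_at_random_edge(tree, labels[idx], rng)
    return tree


def _attach_at_random_edge(tree: Tree, leaf: str, rng) -> Tree:
    nodes = list(tree.postorder())
    # edges: one per non-root node, plus the root edge
    choice = int(rng.integers(0, len(nodes)))
    parents = tree.parent_map()
    t = tree.copy()
    # re-derive the chosen node in the copy by position
    nodes_copy = list(t.postorder())
    target = nodes_copy[choice]
    if parents[id(nodes[choice])] is None:
        t.root = Node(children=[t.root, Node(label=leaf)])
        return t
    parent = t.parent_map()[id(target)]
    i = parent.children.index(target)
    parent.children[i] = Node(children=[target, Node(label=leaf)])
    return t


def rf_distance(a: Tree, b: Tree) -> int:
    """Rooted Robinson–Foulds distance: symmetric difference of the
    non-trivial clade sets (root clade excluded)."""
    if a.leaf_set != b.leaf_set:
        raise ValueError("trees are on different leaf sets")
    ca = a.clades(include_root=False)
    cb = b.clades(include_root=False)
    return len(ca ^ cb)


# ---------------------------------------------------------------------------
# topological moves (used by the supertree search and the noise generator)


def nni_neighbors(tree: Tree) -> Iterator[Tree]:
    """All nearest-neighbour-interchange neighbours of a rooted bifurcating
    tree.  For each internal non-root node v with sibling s, the two swaps
    of s with one child of v are generated."""
    parents = tree.parent_map()
    nodes = list(tree.postorder())
    for pos, node in enumerate(nodes):
        if node.is_leaf or parents[id(node)] is None:
            continue
        parent = parents[id(node)]
        if len(parent.children) != 2 or len(node.children) != 2:
            continue
        for swap_idx in (0, 1):
            t = tree.copy()
            nodes_copy = list(t.postorder())
            v = nodes_copy[pos]
            p = t.parent_map()[id(v)]
            sib_i = 1 - p.children.index(v)
            s = p.children[sib_i]
            c = v.children[swap_idx]
            v.children[swap_idx] = s
            p.children[sib_i] = c
            yield t


def spr_neighbors(tree: Tree) -> Iterator[Tree]:
    """All subtree-prune-and-regraft neighbours of a rooted bifurcating tree.

    Every non-root subtree is pruned and reattached on every edge of the
    remaining tree (including above the root).  Moves recreating the
    original topology are filtered out by the caller if needed.
    """
    nodes = list(tree.postorder())
    parents = tree.parent_map()
    for pos, node in enumerate(nodes):
        if parents[id(node)] is None:
            continue
        t0 = tree.copy()
        nodes_copy = list(t0.postorder())
        prune = nodes_copy[pos]
        pmap = t0.parent_map()
        parent = pmap[id(prune)]
        grand = pmap[id(parent)]
        sib = parent.children[1 - parent.children.index(prune)]
        if grand is None:
            remainder = Tree(sib, tree_id=t0.tree_id)
        else:
            grand.children[grand.children.index(parent)] = sib
            remainder = Tree(t0.root, tree_id=t0.tree_id)
        rem_nodes = list(remainder.postorder())
        rem_parents = remainder.parent_map()
        for rpos, target in enumerate(rem_nodes):
            r = remainder.copy()
            sub = prune.copy()
            r_nodes = list(r.postorder())
            tgt = r_nodes[rpos]
            if rem_parents[id(target)] is None:
                yield Tree(Node(children=[r.root, sub]), tree_id=tree.tree_id)
            else:
                par = r.parent_map()[id(tgt)]
                par.children[par.children.index(tgt)] = Node(
                    children=[tgt, sub])
                yield r


def random_nni(tree: Tree, k: int, rng) -> Tree:
    """Apply ``k`` random NNI moves (for generating noisy input trees)."""
    t = tree
    for _ in range(k):
        neigh = list(nni_neighbors(t))
        if not neigh:
            return t
        t = neigh[int(rng.integers(0, len(neigh)))]
    return t
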