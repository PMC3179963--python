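"""Matrix-representation supertree construction.

Input trees are recoded as a binary character matrix (Baum–Ragan coding:
one column per non-root internal node, descendants scored 1, the source
tree's other taxa 0, taxa absent from that source missing).  A supertree is
then sought either by parsimony over the matrix (MRP: minimize Fitch steps)
or by compatibility (MRC: maximize the number of columns whose 1-state taxa
form a clade of the candidate tree restricted to the column's scored taxa).

The search is a random-addition-order stepwise build followed by
hill-climbing over NNI and SPR neighbourhoods, restarted from independent
addition orders; all distinct best-scoring topologies encountered anywhere
during the search are retained (capped).  The designated outgroup is
constrained to attach at the root as sister to everything else.  Equally
optimal trees are summarized by a majority-rule consensus extended with the
most frequent compatible minority clades, resolved to a fully bifurcating
tree (diversification tests downstream require strict bifurcation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

from .taxonomy import TreeSet
from .trees import Node, Tree, nni_neighbors, spr_neighbors

__all__ = [
    "MatrixColumn",
    "CharacterMatrix",
    "SearchResult",
    "ConsensusTree",
    "mrp_encode",
    "parsimony_length",
    "compatibility_count",
    "search",
    "majority_rule_plus",
    "tree_from_clades",
]

Criterion = Literal["mrp", "mrc"]

# Fitch state sets for a binary character, encoded as 2-bit masks
_STATE0 = np.uint8(1)
_STATE1 = np.uint8(2)
_MISSING = np.uint8(3)


@dataclass(frozen=True)
class MatrixColumn:
    source_tree_id: str
    ones: frozenset[str]
    present: frozenset[str]  # taxa with a non-missing state (includes ones)

    def __post_init__(self):
        if not self.ones or not (self.present - self.ones):
            raise ValueError(
                f"column from {self.source_tree_id} is uninformative "
                "(needs at least one taxon in each state)")
        if not self.ones <= self.present:
            raise ValueError("ones must be a subset of present")


@dataclass
class CharacterMatrix:
    taxa: tuple[str, ...]
    columns: list[MatrixColumn]
    outgroup: str | None = None
    _leaf_arrays: dict[str, np.ndarray] | None = field(
        default=None, repr=False, compare=False)

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def leaf_state_arrays(self) -> dict[str, np.ndarray]:
        """Per-taxon Fitch state-set vectors over all columns (cached)."""
        if self._leaf_arrays is None:
            m = len(self.columns)
            arrays = {t: np.full(m, _MISSING, dtype=np.uint8)
                      for t in self.taxa}
            for j, col in enumerate(self.columns):
                for t in col.present:
                    arrays[t][j] = _STATE1 if t in col.ones else _STATE0
            self._leaf_arrays = arrays
        return self._leaf_arrays

    def to_nexus(self) -> str:
        """NEXUS DATA block, symbols "01", missing "?" — the interchange
        format parsimony programs expect."""
        lines = ["#NEXUS", "BEGIN DATA;",
                 f"    DIMENSIONS NTAX={len(self.taxa)} "
                 f"NCHAR={self.n_columns};",
                 "    FORMAT DATATYPE=STANDARD SYMBOLS=\"01\" MISSING=?;",
                 "    MATRIX"]
        width = max(len(t) for t in self.taxa) + 2
        for t in self.taxa:
            states = "".join(
                "1" if t in c.ones else ("0" if t in c.present else "?")
                for c in self.columns)
            lines.append(f"    {t:<{width}}{states}")
        lines += ["    ;", "END;", ""]
        return "\n".join(lines)


def mrp_encode(trees: TreeSet | Sequence[Tree], outgroup: str
               ) -> CharacterMatrix:
    """Baum–Ragan binary coding of a standardized tree set.

    The outgroup row is scored 0 in every column (appended as 0 where the
    source tree lacks it), anchoring the root of the supertree search.
    """
    tree_list = list(trees)
    taxa = sorted(set().union(*(t.leaf_set for t in tree_list)) | {outgroup})
    columns: list[MatrixColumn] = []
    for tree in tree_list:
        tid = tree.tree_id or "<anonymous>"
        present = frozenset(tree.leaf_set | {outgroup})
        below = tree.clade_map()
        root_clade = tree.leaf_set
        for node in tree.postorder():
            if node.is_leaf:
                continue
            clade = below[id(node)]
            if clade == root_clade:
                continue  # root column carries no grouping information
            ones = frozenset(clade - {outgroup}) if outgroup in clade else \
                frozenset(clade)
            if not ones or not (present - ones):
                continue
            columns.append(MatrixColumn(tid, ones, present))
    return CharacterMatrix(tuple(taxa), columns, outgroup=outgroup)


# ---------------------------------------------------------------------------
# scoring


def _fitch_steps(tree: Tree, matrix: CharacterMatrix) -> int:
    arrays = matrix.leaf_state_arrays()
    m = matrix.n_columns
    steps = np.zeros(m, dtype=np.int64)
    below: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            arr = arrays.get(node.label)
            below[id(node)] = arr if arr is not None else np.full(
                m, _MISSING, dtype=np.uint8)
        else:
            acc = below[id(node.children[0])]
            for child in node.children[1:]:
                b = below[id(child)]
                inter = acc & b
                empty = inter == 0
                steps += empty
                acc = np.where(empty, acc | b, inter)
            below[id(node)] = acc
    return int(steps.sum())


def _check_coverage(tree: Tree, matrix: CharacterMatrix) -> None:
    leaf_set = tree.leaf_set
    scored = set().union(*(c.present for c in matrix.columns)) if \
        matrix.columns else set()
    missing = scored - leaf_set
    if missing:
        raise ValueError(
            f"matrix taxa absent from tree: {sorted(missing)}")


def parsimony_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Fitch parsimony length of the matrix on a rooted tree.

    Missing entries contribute the full state set {0,1} and hence never
    force a step on their own.
    """
    _check_coverage(tree, matrix)
    return _fitch_steps(tree, matrix)


def compatibility_count(tree: Tree, matrix: CharacterMatrix) -> int:
    """Number of columns whose 1-taxa form a clade of the tree restricted
    to the column's scored taxa."""
    _check_coverage(tree, matrix)
    return _restricted_clade_hits(tree, matrix)


def _restricted_clade_hits(tree: Tree, matrix: CharacterMatrix) -> int:
    clades = tree.clades(include_leaves=True, include_root=True)
    hits = 0
    for col in matrix.columns:
        present = col.present & tree.leaf_set
        ones = col.ones & tree.leaf_set
        if not ones or not (present - ones):
            continue  # column vacuous on this leaf set
        if any(c & present == ones for c in clades):
            hits += 1
    return hits


def _score(tree: Tree, matrix: CharacterMatrix, criterion: Criterion) -> int:
    """Raw score (no coverage check; used on partial trees during stepwise
    addition)."""
    if criterion == "mrp":
        return _fitch_steps(tree, matrix)
    return _restricted_clade_hits(tree, matrix)


def _better(a: int, b: int, criterion: Criterion) -> bool:
    return a < b if criterion == "mrp" else a > b


# ---------------------------------------------------------------------------
# search


@dataclass
class SearchResult:
    optimal_trees: list[Tree]
    score: int
    criterion: Criterion
    seed: int
    restarts: int
    hit_cap: bool = False

    @property
    def leaf_set(self) -> frozenset[str]:
        return self.optimal_trees[0].leaf_set


def _canonical_key(tree: Tree) -> frozenset[frozenset[str]]:
    return frozenset(tree.clades(include_root=False))


def _attach_positions(tree: Tree, leaf: str) -> Iterator[Tree]:
    """All trees obtained by attaching ``leaf`` on each edge (root edge
    included), in deterministic traversal order."""
    yield Tree(Node(children=[tree.root.copy(), Node(label=leaf)]),
               tree_id=tree.tree_id)
    nodes = list(tree.postorder())
    parents = tree.parent_map()
    for pos, node in enumerate(nodes):
        if parents[id(node)] is None:
            continue
        t = tree.copy()
        nodes_copy = list(t.postorder())
        target = nodes_copy[pos]
        parent = t.parent_map()[id(target)]
        parent.children[parent.children.index(target)] = Node(
            children=[target, Node(label=leaf)])
        yield t


def _with_outgroup(ingroup_tree: Tree, outgroup: str | None) -> Tree:
    if outgroup is None:
        return ingroup_tree
    return Tree(Node(children=[ingroup_tree.root, Node(label=outgroup)]))


class _BestSet:
    """Tracks the best score seen and the distinct topologies achieving it."""

    def __init__(self, criterion: Criterion, cap: int):
        self.criterion = criterion
        self.cap = cap
        self.score: int | None = None
        self.trees: dict[frozenset, Tree] = {}
        self.hit_cap = False

    def offer(self, tree: Tree, score: int) -> None:
        if self.score is None or _better(score, self.score, self.criterion):
            self.score = score
            self.trees = {}
            self.hit_cap = False
        if score == self.score:
            key = _canonical_key(tree)
            if key not in self.trees:
                if len(self.trees) >= self.cap:
                    self.hit_cap = True
                else:
                    self.trees[key] = tree.copy()


def search(matrix: CharacterMatrix, criterion: Criterion = "mrp",
           restarts: int = 10, seed: int = 0,
           max_optimal: int = 1000) -> SearchResult:
    """Heuristic supertree search over the character matrix.

    Each restart builds a starting tree by greedy stepwise addition in a
    random taxon order, then hill-climbs: steepest-ascent over the NNI
    neighbourhood, falling back to SPR when NNI is exhausted.  Every tree
    evaluated anywhere that ties the best score is collected (up to
    ``max_optimal`` distinct topologies).  Fully deterministic for a given
    seed.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    criterion = criterion.lower()  # type: ignore[assignment]
    if criterion not in ("mrp", "mrc"):
        raise ValueError(f"unknown criterion {criterion!r}")
    rng = np.random.default_rng(seed)
    outgroup = matrix.outgroup
    ingroup = [t for t in matrix.taxa if t != outgroup]
    if len(ingroup) < 2:
        raise ValueError("need at least 2 ingroup taxa")

    best = _BestSet(criterion, max_optimal)

    n_ingroup = len(ingroup)

    def evaluate(ingroup_tree: Tree) -> int:
        full = _with_outgroup(ingroup_tree, outgroup)
        s = _score(full, matrix, criterion)
        if ingroup_tree.n_leaves == n_ingroup:  # only complete trees compete
            best.offer(full, s)
        return s

    for _ in range(restarts):
        order = [ingroup[i] for i in rng.permutation(len(ingroup))]
        current = Tree(Node(children=[Node(label=order[0]),
                                      Node(label=order[1])]))
        cur_score = evaluate(current)
        for leaf in order[2:]:
            best_cand: Tree | None = None
            best_s: int | None = None
            for cand in _attach_positions(current, leaf):
                s = evaluate(cand)
                if best_s is None or _better(s, best_s, criterion):
                    best_cand, best_s = cand, s
            current, cur_score = best_cand, best_s  # type: ignore[assignment]

        # hill climb
        improved = True
        while improved:
            improved = False
            for neighbourhood in (nni_neighbors, spr_neighbors):
                move_to: Tree | None = None
                move_score = cur_score
                for cand in neighbourhood(current):
                    s = evaluate(cand)
                    if _better(s, move_score, criterion):
                        move_to, move_score = cand, s
                if move_to is not None:
                    current, cur_score = move_to, move_score
                    improved = True
                    break

    trees = sorted(best.trees.values(), key=lambda t: t.to_newick())
    return SearchResult(optimal_trees=trees, score=best.score,
                        criterion=criterion, seed=seed, restarts=restarts,
                        hit_cap=best.hit_cap)


# ---------------------------------------------------------------------------
# consensus


@dataclass
class ConsensusTree:
    tree: Tree
    clade_frequencies: dict[frozenset[str], float]

    def to_newick(self) -> str:
        labels = {cl: f"{f:.3f}" for cl, f in self.clade_frequencies.items()}
        return self.tree.to_newick(node_labels=labels)


def _compatible(clade: frozenset[str], accepted: Iterable[frozenset[str]]
                ) -> bool:
    return all(clade <= c or c <= clade or not (clade & c)
               for c in accepted)


def tree_from_clades(leaves: Iterable[str],
                     clades: Iterable[frozenset[str]]) -> Tree:
    """Build the rooted tree displaying exactly a pairwise-compatible clade
    set (plus trivial clades)."""
    leaf_set = frozenset(leaves)
    nontrivial = sorted(
        {c for c in clades if 1 < len(c) < len(leaf_set)},
        key=lambda c: (-len(c), sorted(c)))

    def build(members: frozenset[str],
              pool: list[frozenset[str]]) -> Node:
        inner = [c for c in pool if c < members]
        maximal = [c for c in inner
                   if not any(c < d for d in inner)]
        covered = frozenset().union(*maximal) if maximal else frozenset()
        children = [build(c, [d for d in inner if d < c]) for c in maximal]
        children += [Node(label=l) for l in sorted(members - covered)]
        if len(children) == 1:
            return children[0]
        return Node(children=children)

    return Tree(build(leaf_set, nontrivial))


def majority_rule_plus(result: SearchResult, resolve: bool = True
                       ) -> ConsensusTree:
    """Majority-rule consensus extended with compatible minority clades.

    Clades appearing in more than half the equally optimal trees are
    included; the remainder are considered in decreasing frequency order
    (ties broken lexicographically on sorted member labels) and added when
    compatible with everything already accepted.  Any residual polytomies
    are resolved deterministically from the search seed so the emitted tree
    is fully bifurcating.
    """
    trees = result.optimal_trees
    if not trees:
        raise ValueError("empty search result")
    leaf_set = trees[0].leaf_set
    for t in trees[1:]:
        if t.leaf_set != leaf_set:
            raise ValueError("optimal trees on differing leaf sets")
    n = len(trees)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for c in t.clades(include_root=False):
            counts[c] = counts.get(c, 0) + 1
    ordered = sorted(counts.items(),
                     key=lambda kv: (-kv[1], sorted(kv[0])))
    accepted: list[frozenset[str]] = []
    freqs: dict[frozenset[str], float] = {leaf_set: 1.0}
    for clade, count in ordered:
        if count * 2 > n or _compatible(clade, accepted):
            if _compatible(clade, accepted):
                accepted.append(clade)
                freqs[clade] = count / n
    tree = tree_from_clades(leaf_set, accepted)
    if resolve and not tree.is_bifurcating():
        rng = np.random.default_rng(result.seed)
        tree = tree.resolve_polytomies(rng)
        for c in tree.clades(include_root=False):
            freqs.setdefault(c, 0.0)
    return ConsensusTree(tree=tree, clade_frequencies=freqs)
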