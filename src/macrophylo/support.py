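"""Nodal support of a supertree against its input trees: the V and V+ indices.

Each supertree clade is scored against every input tree after restricting
the clade to the taxa that tree samples.  An input tree *supports* the node
when it displays the restricted clade exactly, *conflicts* when no
refinement of the input tree could display it, *permits* when the clade is
compatible but not displayed (a polytomy, say), and is *irrelevant* when
too few of its taxa are involved for the node to say anything.

V   = (s − q) / (s + q)                 over supporting / conflicting trees
V+  = (s + p − q) / (s + p + q)         permitting trees credited as support

Both run from −1 (all relevant trees conflict) to +1 (all support); the
mean over nodes summarizes whole-tree support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .supertree import ConsensusTree
from .taxonomy import TreeSet
from .trees import Tree

__all__ = [
    "classify_tree_vs_clade",
    "v_scores",
    "NodeSupport",
    "SupportReport",
]

Verdict = Literal["supports", "conflicts", "permits", "irrelevant"]


def classify_tree_vs_clade(input_tree: Tree, clade: frozenset[str],
                           full_taxa: frozenset[str]) -> Verdict:
    """Classify one input tree's relationship to one supertree clade.

    The clade is first restricted to the input tree's leaves; with fewer
    than two clade taxa, or no outside taxon, the tree cannot bear on the
    grouping and is irrelevant.
    """
    leaves = input_tree.leaf_set
    restricted = frozenset(clade & leaves)
    outside = leaves - restricted
    if len(restricted) < 2 or len(outside) < 1:
        return "irrelevant"
    clades = input_tree.clades(include_leaves=True, include_root=True)
    if restricted in clades:
        return "supports"
    if all(restricted <= c or c <= restricted or not (restricted & c)
           for c in clades):
        return "permits"
    return "conflicts"


@dataclass(frozen=True)
class NodeSupport:
    clade: frozenset[str]
    s: int
    q: int
    perm: int
    irrelevant: int

    @property
    def v(self) -> float | None:
        if self.s + self.q == 0:
            return None
        return (self.s - self.q) / (self.s + self.q)

    @property
    def v_plus(self) -> float | None:
        denom = self.s + self.perm + self.q
        if denom == 0:
            return None
        return (self.s + self.perm - self.q) / denom


@dataclass
class SupportReport:
    per_node: list[NodeSupport]
    n_input_trees: int

    @property
    def tree_v(self) -> float | None:
        vals = [ns.v for ns in self.per_node if ns.v is not None]
        return sum(vals) / len(vals) if vals else None

    @property
    def tree_v_plus(self) -> float | None:
        vals = [ns.v_plus for ns in self.per_node if ns.v_plus is not None]
        return sum(vals) / len(vals) if vals else None

    def as_rows(self) -> list[dict]:
        rows = []
        for ns in sorted(self.per_node, key=lambda x: sorted(x.clade)):
            rows.append({
                "clade": ";".join(sorted(ns.clade)),
                "s": ns.s, "q": ns.q, "perm": ns.perm,
                "irrelevant": ns.irrelevant,
                "V": "" if ns.v is None else f"{ns.v:.4f}",
                "V_plus": "" if ns.v_plus is None else f"{ns.v_plus:.4f}",
            })
        return rows

    def annotated_newick(self, supertree: Tree) -> str:
        labels = {ns.clade: ("" if ns.v is None else f"{ns.v:.3f}")
                  for ns in self.per_node}
        return supertree.to_newick(node_labels=labels)


def v_scores(supertree: Tree | ConsensusTree, trees: TreeSet | Iterable[Tree]
             ) -> SupportReport:
    """Score every non-root internal clade of the supertree against the
    input set.  Node V is null (and excluded from the tree mean) when no
    input tree is relevant in the support/conflict sense."""
    if isinstance(supertree, ConsensusTree):
        supertree = supertree.tree
    input_trees = list(trees)
    full_taxa = supertree.leaf_set
    per_node: list[NodeSupport] = []
    for clade in sorted(supertree.clades(include_root=False),
                        key=lambda c: (len(c), sorted(c))):
        s = q = perm = irr = 0
        for it in input_trees:
            verdict = classify_tree_vs_clade(it, clade, full_taxa)
            if verdict == "supports":
                s += 1
            elif verdict == "conflicts":
                q += 1
            elif verdict == "permits":
                perm += 1
            else:
                irr += 1
        per_node.append(NodeSupport(clade, s, q, perm, irr))
    return SupportReport(per_node=per_node, n_input_trees=len(input_trees))
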