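"""Taxonomic standardization of input trees.

Source phylogenies use genus- or species-level tips, outdated family names
and synonyms.  Before supertree construction every tree is reduced to
one-leaf-per-valid-family form: tip names are resolved through a user
taxonomy (valid names, synonyms, member genera), same-family tips are
condensed to a single leaf where the family is mono- or paraphyletic in
that tree, and families whose tips cannot be condensed without rearranging
other taxa (polyphyletic placements) are removed as unreliably placed.

The paraphyly test used here is deliberately strict: a family's tips are
condensable when the other leaves inside the family's smallest enclosing
clade form a single nested clade (or none, i.e. monophyly).  Anything less
tidy — tips split across the deepest divergence of the tree, or interleaved
with several foreign groups — is treated as uncertain placement and the
family is dropped from that input tree.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .trees import Node, Tree

__all__ = [
    "Taxonomy",
    "TaxonomyError",
    "TreeSet",
    "load_taxonomy",
    "apply_taxonomy",
    "collapse_to_families",
    "standardize_trees",
]

VALID_STATUSES = {"valid", "synonym", "member_genus", "outgroup"}


class TaxonomyError(ValueError):
    pass


@dataclass(frozen=True)
class Taxonomy:
    """Mapping from tip names (valid names, synonyms, genera) to valid
    family names, with a designated outgroup family."""

    entries: tuple[tuple[str, str, str], ...]
    outgroup: str

    def __post_init__(self):
        seen: dict[str, str] = {}
        for name, family, status in self.entries:
            if status not in VALID_STATUSES:
                raise TaxonomyError(f"unknown status {status!r} for {name}")
            if name in seen and seen[name] != family:
                raise TaxonomyError(
                    f"name {name!r} maps to both {seen[name]!r} and "
                    f"{family!r}")
            seen[name] = family
        if self.outgroup not in self.valid_families:
            raise TaxonomyError(
                f"outgroup {self.outgroup!r} is not a valid family")

    @property
    def valid_families(self) -> frozenset[str]:
        return frozenset(fam for _, fam, status in self.entries
                         if status in ("valid", "outgroup"))

    @property
    def lookup(self) -> dict[str, str]:
        return {name: family for name, family, _ in self.entries}

    def resolve(self, name: str) -> str:
        try:
            return self.lookup[name]
        except KeyError:
            raise TaxonomyError(f"unresolved taxon name {name!r}") from None


def load_taxonomy(path: str | Path) -> Taxonomy:
    """Read a 3-column delimited file (name, valid_family, status).

    The outgroup is the row whose status is ``outgroup``; exactly one is
    required.  Lines starting with ``#`` and a header row are skipped.
    """
    entries: list[tuple[str, str, str]] = []
    outgroup: str | None = None
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if row[0].lower() == "name":
                continue
            if len(row) < 3:
                raise TaxonomyError(f"{path}: bad row {row!r}")
            name, family, status = row[0].strip(), row[1].strip(), \
                row[2].strip()
            entries.append((name, family, status))
            if status == "outgroup":
                if outgroup is not None:
                    raise TaxonomyError(f"{path}: multiple outgroup rows")
                outgroup = family
    if outgroup is None:
        raise TaxonomyError(f"{path}: no outgroup row")
    return Taxonomy(tuple(entries), outgroup)


@dataclass
class TreeSet:
    """A curated set of standardized input trees plus the union of their
    leaves (all valid family names after standardization)."""

    trees: list[Tree] = field(default_factory=list)

    @property
    def leaf_union(self) -> frozenset[str]:
        out: set[str] = set()
        for t in self.trees:
            out |= t.leaf_set
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)


def apply_taxonomy(tree: Tree, tax: Taxonomy) -> Tree:
    """Rename every leaf to its valid family name.

    Duplicate family labels are permitted at this stage (they are resolved
    by :func:`collapse_to_families`).  Unresolvable labels raise
    :class:`TaxonomyError` listing all offenders.
    """
    lookup = tax.lookup
    unresolved = sorted({lbl for lbl in tree.leaf_labels if lbl not in lookup})
    if unresolved:
        raise TaxonomyError(
            f"tree {tree.tree_id or '<anonymous>'}: unresolved labels "
            f"{unresolved}")
    t = tree.copy()
    for leaf in t.leaves():
        leaf.label = lookup[leaf.label]
    return t


def _family_leaf_counts(tree: Tree) -> dict[str, int]:
    counts: dict[str, int] = {}
    for lbl in tree.leaf_labels:
        counts[lbl] = counts.get(lbl, 0) + 1
    return counts


def collapse_to_families(tree: Tree, min_leaves: int = 3
                         ) -> tuple[Tree | None, list[str]]:
    """Condense each family's leaves to a single leaf, or remove the family.

    A family with several leaves is *condensable* when, inside the smallest
    clade containing all its leaves, the remaining leaves either vanish
    (monophyly) or themselves form one clade (single-interloper paraphyly);
    the family is then replaced by a single leaf sister to that interloper
    clade.  Any other arrangement is treated as polyphyletic and the family
    is deleted from the tree.

    Returns ``(tree, log)``; the tree is ``None`` (discarded) if fewer than
    ``min_leaves`` leaves survive.  The log records removals and discards.
    """
    # leaves carry duplicate labels here, so give each an interim unique tag
    log: list[str] = []
    t = tree.copy()
    tid = tree.tree_id or "<anonymous>"

    changed = True
    while changed:
        changed = False
        counts = _family_leaf_counts(t)
        for family in sorted(f for f, c in counts.items() if c > 1):
            result = _condense_family(t, family)
            if result is None:
                # polyphyletic: remove every leaf of this family
                log.append(f"{tid}: family {family} polyphyletic, removed")
                survivors = [lbl for lbl in t.leaf_labels if lbl != family]
                if not survivors:
                    log.append(f"{tid}: discarded (<{min_leaves} leaves)")
                    return None, log
                t = t.remove_leaves([family])
            else:
                t = result
            changed = True
            break
    if t.n_leaves < min_leaves:
        log.append(f"{tid}: discarded (<{min_leaves} leaves)")
        return None, log
    return t, log


def _condense_family(tree: Tree, family: str) -> Tree | None:
    """Condense one multi-leaf family in place; None means polyphyletic."""
    # tag duplicate leaves uniquely so set machinery can address them
    t = tree.copy()
    tags: list[str] = []
    k = 0
    for leaf in t.leaves():
        if leaf.label == family:
            leaf.label = f"{family}@@{k}"
            tags.append(leaf.label)
            k += 1
    below = t.clade_map()
    fam_set = frozenset(tags)
    # smallest clade containing all family leaves
    mrca_clade: frozenset[str] | None = None
    for node in t.postorder():
        cl = below[id(node)]
        if fam_set <= cl and (mrca_clade is None or len(cl) < len(mrca_clade)):
            mrca_clade = cl
    assert mrca_clade is not None
    complement = mrca_clade - fam_set
    if complement and complement not in below.values():
        return None  # interlopers do not form a single clade: polyphyletic

    def rebuild(node: Node) -> Node:
        cl = below[id(node)]
        if cl == mrca_clade:
            if not complement:
                return Node(label=family)
            comp_node = _find_clade_node(node, below, complement)
            return Node(children=[Node(label=family), comp_node.copy()])
        if node.is_leaf:
            return Node(node.label, None, node.age)
        return Node(node.label, [rebuild(c) for c in node.children], node.age)

    return Tree(rebuild(t.root), tree_id=tree.tree_id)


def _find_clade_node(root: Node, below: dict[int, frozenset[str]],
                     clade: frozenset[str]) -> Node:
    stack = [root]
    while stack:
        node = stack.pop()
        if below[id(node)] == clade:
            return node
        stack.extend(node.children)
    raise AssertionError("clade node not found")


def standardize_trees(trees: Sequence[Tree], tax: Taxonomy,
                      min_leaves: int = 3) -> tuple[TreeSet, list[str]]:
    """Apply the taxonomy and family collapsing to every input tree.

    Trees that end up with fewer than ``min_leaves`` leaves are dropped with
    a log entry rather than raising, matching how a curated literature
    compilation treats uninformative sources.
    """
    out = TreeSet()
    log: list[str] = []
    valid = tax.valid_families
    for tree in trees:
        renamed = apply_taxonomy(tree, tax)
        collapsed, tree_log = collapse_to_families(renamed,
                                                   min_leaves=min_leaves)
        log.extend(tree_log)
        if collapsed is None:
            continue
        stray = collapsed.leaf_set - valid
        if stray:
            raise TaxonomyError(
                f"tree {tree.tree_id}: non-family labels after taxonomy "
                f"application: {sorted(stray)}")
        collapsed.validate()
        out.trees.append(collapsed)
    return out, log
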