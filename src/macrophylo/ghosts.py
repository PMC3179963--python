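"""Ghost-range inference: phylogeny-adjusted origination dates.

Sister lineages diverge simultaneously, so both must already exist when
the older of the two first appears in the fossil record.  Taking the tree
as correct and the record as incomplete, each family's origination is
pulled back to the first appearance implied by its sister clade whenever
that is older:

    adjusted_fad(f) = max(fad(f), clade_fad(sister(f)))
                    = clade_fad(parent(f))

where ``clade_fad`` is the oldest (raw) first appearance among a clade's
member families.  Only the divergence from the immediate sister is
credited to the family itself; older stem segments belong to ancestral
lineages.  Last appearances are never altered.  Families absent from the
tree pass through unchanged so the family-level richness curve can still
include them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

from .trees import Node, Tree

__all__ = [
    "FossilRange",
    "FossilRangeTable",
    "load_ranges",
    "clade_fad",
    "adjust_originations",
    "extension_summary",
    "ExtensionSummary",
]


@dataclass(frozen=True)
class FossilRange:
    """Stratigraphic range of one family, in Ma before present."""

    fad: float              # first appearance (oldest), Ma
    lad: float              # last appearance (0 for extant), Ma
    extant: bool
    in_tree: bool = True

    def __post_init__(self):
        if self.fad < self.lad:
            raise ValueError(f"fad {self.fad} < lad {self.lad}")
        if self.extant and self.lad != 0:
            raise ValueError("extant families must have lad = 0")
        if self.lad < 0:
            raise ValueError("negative age")


class FossilRangeTable(dict):
    """family -> :class:`FossilRange`."""

    @property
    def extant_families(self) -> frozenset[str]:
        return frozenset(f for f, r in self.items() if r.extant)


def load_ranges(path: str | Path) -> FossilRangeTable:
    """Delimited text: family, fad_ma, lad_ma, extant(0/1)[, in_tree(0/1)]."""
    table = FossilRangeTable()
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0].lower() == \
                    "family":
                continue
            fam = row[0].strip()
            fad, lad = float(row[1]), float(row[2])
            extant = bool(int(row[3]))
            in_tree = bool(int(row[4])) if len(row) > 4 else True
            table[fam] = FossilRange(fad, lad, extant, in_tree)
    return table


def clade_fad(tree: Tree, node: Node, ranges: FossilRangeTable) -> float:
    """Oldest first appearance among the families below ``node``."""
    leaves = [n.label for n in Tree(node).leaves()]
    missing = [l for l in leaves if l not in ranges]
    if missing:
        raise KeyError(f"no fossil range for families {missing}")
    return max(ranges[l].fad for l in leaves)


def adjust_originations(tree: Tree, ranges: FossilRangeTable
                        ) -> FossilRangeTable:
    """Return a copy of the range table with phylogeny-adjusted FADs.

    Leaves of the tree must all be present in the table; families not in
    the tree are passed through unchanged.  Polytomies are allowed — the
    sister clade is then the union of all siblings.
    """
    missing = [l for l in tree.leaf_labels if l not in ranges]
    if missing:
        raise KeyError(f"no fossil range for tree families {missing}")
    adjusted = FossilRangeTable(
        {f: r for f, r in ranges.items()})
    # oldest raw fad below each node
    oldest: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_leaf:
            oldest[id(node)] = ranges[node.label].fad
        else:
            oldest[id(node)] = max(oldest[id(c)] for c in node.children)
    parents = tree.parent_map()
    for leaf in tree.leaves():
        parent = parents[id(leaf)]
        if parent is None:
            continue  # single-leaf tree: no sister, nothing to adjust
        new_fad = max(ranges[leaf.label].fad, oldest[id(parent)])
        adjusted[leaf.label] = replace(ranges[leaf.label], fad=new_fad)
    return adjusted


@dataclass
class ExtensionSummary:
    extensions: dict[str, float]     # family -> adjusted_fad - fad (>= 0)
    n_extended: int
    max_extension: float
    max_family: str | None

    def as_rows(self) -> list[dict]:
        return [{"family": f, "extension_my": f"{e:.4g}"}
                for f, e in sorted(self.extensions.items())]


def extension_summary(raw: FossilRangeTable, adjusted: FossilRangeTable
                      ) -> ExtensionSummary:
    """Per-family range extensions produced by ghost-range adjustment."""
    if set(raw) != set(adjusted):
        raise ValueError("tables list different families")
    ext = {f: adjusted[f].fad - raw[f].fad for f in raw}
    neg = [f for f, e in ext.items() if e < -1e-12]
    if neg:
        raise ValueError(f"adjusted fad earlier than raw for {neg}")
    extended = {f: e for f, e in ext.items() if e > 0}
    if extended:
        max_family = max(extended, key=lambda f: (extended[f], f))
        max_ext = extended[max_family]
    else:
        max_family, max_ext = None, 0.0
    return ExtensionSummary(extensions=ext, n_extended=len(extended),
                            max_extension=max_ext, max_family=max_family)
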