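"""Sister-clade diversification-shift detection (Slowinski–Guyer test).

Under an equal-rates null, the species total N = N1 + N2 of two same-age
sister clades is split uniformly over (1, N−1) … (N−1, 1), so the
probability of a split at least as lopsided as the one observed is

    p = min(1, 2 * N_small / (N_small + N_large − 1)).

Every extant sister pair of a fully bifurcating supertree is tested.  A
significant imbalance deep in the tree would drag significance rootward
("trickle-down"): once a node is significant, the richer daughter's
contribution to all more-rootward sums is replaced by the poorer
daughter's, so the node passes 2·min upward and cannot re-trigger at its
ancestors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .trees import Tree

__all__ = [
    "RichnessTable",
    "load_richness",
    "sg_probability",
    "prune_to_extant",
    "detect_shifts",
    "SisterComparison",
    "ShiftReport",
]


class RichnessTable(dict):
    """family -> described extant species count (positive integers)."""

    def __init__(self, data: dict[str, int] | Iterable[tuple[str, int]] = ()):
        super().__init__(data)
        for fam, n in self.items():
            if not isinstance(n, int) or n < 1:
                raise ValueError(
                    f"richness for {fam!r} must be a positive integer, "
                    f"got {n!r}")

    def clade_sum(self, families: Iterable[str]) -> int:
        total = 0
        for fam in families:
            if fam not in self:
                raise KeyError(f"no species richness for family {fam!r}")
            total += self[fam]
        return total


def load_richness(path: str | Path | None = None) -> RichnessTable:
    """2-column delimited text: family <TAB> species_count.

    With no path, returns the packaged extant-odonate family table.
    """
    if path is None:
        import importlib.resources
        path_obj = importlib.resources.files("macrophylo.data") / \
            "odonata_richness.tsv"
        text = path_obj.read_text()
    else:
        text = Path(path).read_text()
    data: dict[str, int] = {}
    for row in csv.reader(text.splitlines(), delimiter="\t"):
            if not row or row[0].startswith("#") or row[0].lower() == \
                    "family":
                continue
            data[row[0].strip()] = int(row[1])
    return RichnessTable(data)


def sg_probability(n_small: int, n_large: int) -> float:
    """Slowinski–Guyer tail probability for a sister-pair richness split.

    Arguments are ordered internally, so the function is symmetric.
    """
    if n_small < 1 or n_large < 1:
        raise ValueError("clade richness must be positive")
    n_small, n_large = sorted((n_small, n_large))
    return min(1.0, 2.0 * n_small / (n_large + n_small - 1))


def prune_to_extant(tree: Tree, extant: Iterable[str]) -> Tree:
    """Drop fossil-only leaves and suppress the resulting degree-2 nodes."""
    extant = set(extant)
    keep = tree.leaf_set & extant
    if len(keep) < 2:
        raise ValueError(
            f"fewer than 2 extant leaves remain ({sorted(keep)})")
    return tree.restrict_to(keep)


@dataclass(frozen=True)
class SisterComparison:
    clade_a: frozenset[str]
    clade_b: frozenset[str]
    n_a: int                 # raw richness sums
    n_b: int
    corrected_a: int         # sums actually compared (post trickle-down)
    corrected_b: int
    p: float
    significant: bool
    direction: str | None    # "upshift_in_richer" | "downshift_in_poorer"

    @property
    def node(self) -> frozenset[str]:
        return self.clade_a | self.clade_b


@dataclass
class ShiftReport:
    comparisons: list[SisterComparison]
    alpha: float

    @property
    def significant(self) -> list[SisterComparison]:
        return [c for c in self.comparisons if c.significant]

    def as_rows(self) -> list[dict]:
        rows = []
        for c in sorted(self.comparisons,
                        key=lambda x: (len(x.node), sorted(x.node))):
            rows.append({
                "clade_a": ";".join(sorted(c.clade_a)),
                "clade_b": ";".join(sorted(c.clade_b)),
                "n_a": c.n_a, "n_b": c.n_b,
                "corrected_a": c.corrected_a, "corrected_b": c.corrected_b,
                "p": f"{c.p:.6g}",
                "significant": int(c.significant),
                "direction": c.direction or "",
            })
        return rows


def detect_shifts(tree: Tree, richness: RichnessTable,
                  alpha: float = 0.05,
                  trickle_down: bool = True) -> ShiftReport:
    """Test every sister pair of a bifurcating extant tree for a
    diversification-rate shift.

    Nodes are visited tips-to-root in a single pass.  With
    ``trickle_down`` enabled (the default), a significant node passes
    ``2 * min`` richness rootward instead of its raw sum, which removes the
    spurious significance a single strong shift would otherwise induce at
    every ancestor.

    Direction labelling: the test itself is symmetric, so the reported
    direction is a descriptive tag — "downshift_in_poorer" when the poorer
    daughter's per-lineage richness falls below the tree-wide median,
    otherwise "upshift_in_richer".
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    for leaf in tree.leaf_labels:
        if leaf not in richness:
            raise KeyError(f"no species richness for family {leaf!r}")
    if not tree.is_bifurcating():
        raise ValueError(
            "shift detection requires a fully bifurcating tree")

    median = _median(sorted(richness[f] for f in tree.leaf_labels))
    comparisons: list[SisterComparison] = []
    raw: dict[int, int] = {}
    eff: dict[int, int] = {}
    nleaf: dict[int, int] = {}
    below = tree.clade_map()
    for node in tree.postorder():
        if node.is_leaf:
            raw[id(node)] = eff[id(node)] = richness[node.label]
            nleaf[id(node)] = 1
            continue
        a, b = node.children
        ra, rb = raw[id(a)], raw[id(b)]
        ea, eb = eff[id(a)], eff[id(b)]
        p = sg_probability(min(ea, eb), max(ea, eb))
        significant = p < alpha
        direction = None
        if significant:
            if ea <= eb:
                poor_r, poor_n = ra, nleaf[id(a)]
            else:
                poor_r, poor_n = rb, nleaf[id(b)]
            direction = ("downshift_in_poorer"
                         if poor_r / poor_n < median
                         else "upshift_in_richer")
        comparisons.append(SisterComparison(
            clade_a=below[id(a)], clade_b=below[id(b)],
            n_a=ra, n_b=rb, corrected_a=ea, corrected_b=eb,
            p=p, significant=significant, direction=direction))
        raw[id(node)] = ra + rb
        nleaf[id(node)] = nleaf[id(a)] + nleaf[id(b)]
        if significant and trickle_down:
            eff[id(node)] = 2 * min(ea, eb)
        else:
            eff[id(node)] = ea + eb
    return ShiftReport(comparisons=comparisons, alpha=alpha)


def _median(sorted_vals: list[int]) -> float:
    n = len(sorted_vals)
    if n == 0:
        raise ValueError("empty")
    mid = n // 2
    if n % 2:
        return float(sorted_vals[mid])
    return (sorted_vals[mid - 1] + sorted_vals[mid]) / 2.0
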