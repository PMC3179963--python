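import itertools

import numpy as np
import pytest

from macrophylo.supertree import (CharacterMatrix, MatrixColumn,
                                  _score, _with_outgroup, compatibility_count,
                                  majority_rule_plus, mrp_encode,
                                  parsimony_length, search, tree_from_clades)
from macrophylo.taxonomy import TreeSet
from macrophylo.trees import Tree, all_rooted_topologies, parse_newick


def brute_force_fitch(tree, column):
    """Independent parsimony oracle: minimize state changes over every
    assignment of {0,1} to internal nodes (missing leaves free)."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    free_leaves = [n for n in nodes if n.is_leaf and
                   n.label not in column.present]
    parents = tree.parent_map()
    best = None
    for states in itertools.product([0, 1],
                                    repeat=len(internals) +
                                    len(free_leaves)):
        assign = dict(zip([id(n) for n in internals + free_leaves], states))
        for n in nodes:
            if n.is_leaf and n.label in column.present:
                assign[id(n)] = 1 if n.label in column.ones else 0
        changes = sum(1 for n in nodes if parents[id(n)] is not None
                      and assign[id(n)] != assign[id(parents[id(n)])])
        best = changes if best is None else min(best, changes)
    return best


class TestEncoding:
    def test_balanced_four_taxon_tree(self):
        ts = TreeSet([parse_newick("((A,B),(C,D));", tree_id="t")])
        m = mrp_encode(ts, outgroup="OG")
        assert m.n_columns == 2
        sets = {(tuple(sorted(c.ones))) for c in m.columns}
        assert sets == {("A", "B"), ("C", "D")}
        for c in m.columns:
            assert c.present == frozenset("ABCD") | {"OG"}

    def test_star_tree_yields_no_columns(self):
        ts = TreeSet([parse_newick("(A,B,C);", tree_id="t")])
        assert mrp_encode(ts, outgroup="OG").n_columns == 0

    def test_missing_taxon_coded_missing(self):
        ts = TreeSet([parse_newick("((A,B),(C,D));", tree_id="t1"),
                      parse_newick("((A,B),C);", tree_id="t2")])
        m = mrp_encode(ts, outgroup="OG")
        second = [c for c in m.columns if c.source_tree_id == "t2"]
        assert len(second) == 1
        assert second[0].ones == frozenset("AB")
        assert "D" not in second[0].present      # missing, not 0
        assert "OG" in second[0].present          # outgroup appended as 0

    def test_uninformative_column_rejected(self):
        with pytest.raises(ValueError, match="uninformative"):
            MatrixColumn("x", frozenset("AB"), frozenset("AB"))

    def test_nexus_export_contains_matrix(self):
        ts = TreeSet([parse_newick("((A,B),C);", tree_id="t")])
        nex = mrp_encode(ts, outgroup="OG").to_nexus()
        assert "NCHAR=1" in nex and "MISSING=?" in nex


class TestScoring:
    @pytest.fixture()
    def matrix(self):
        return mrp_encode(TreeSet([parse_newick("((A,B),(C,D));",
                                                tree_id="t")]),
                          outgroup="OG")

    def test_perfect_fit_identity(self, matrix):
        t = parse_newick("(((A,B),(C,D)),OG);")
        assert parsimony_length(t, matrix) == matrix.n_columns
        assert compatibility_count(t, matrix) == matrix.n_columns

    def test_wrong_tree_scores(self, matrix):
        t = parse_newick("(((A,C),(B,D)),OG);")
        assert parsimony_length(t, matrix) == 4
        assert compatibility_count(t, matrix) == 0

    def test_missing_taxon_raises(self, matrix):
        with pytest.raises(ValueError, match="absent"):
            parsimony_length(parse_newick("((A,B),(C,OG));"), matrix)

    @pytest.mark.parametrize("newick", [
        "(((A,B),(C,D)),(E,OG));",
        "((((A,C),B),(D,E)),OG);",
        "(((A,(B,E)),(C,D)),OG);",
    ])
    def test_fitch_matches_brute_force(self, newick):
        ts = TreeSet([parse_newick("((A,B),(C,D));", tree_id="t1"),
                      parse_newick("((A,(C,E)),B);", tree_id="t2")])
        m = mrp_encode(ts, outgroup="OG")
        tree = parse_newick(newick)
        expected = sum(brute_force_fitch(tree, c) for c in m.columns)
        assert parsimony_length(tree, m) == expected

    def test_score_bounds(self):
        # MRP >= n_columns, MRC <= n_columns for every candidate topology
        ts = TreeSet([parse_newick("((A,B),(C,D));", tree_id="t1"),
                      parse_newick("((A,C),(B,D));", tree_id="t2")])
        m = mrp_encode(ts, outgroup="OG")
        for t in all_rooted_topologies(["A", "B", "C", "D"]):
            full = _with_outgroup(t, "OG")
            assert parsimony_length(full, m) >= m.n_columns
            assert compatibility_count(full, m) <= m.n_columns


class TestSearch:
    def test_self_consistency(self):
        ts = TreeSet([parse_newick("(((A,B),C),(D,E));", tree_id="t")])
        m = mrp_encode(ts, outgroup="OG")
        for crit in ("mrp", "mrc"):
            res = search(m, crit, restarts=5, seed=1)
            assert res.score == m.n_columns
            keys = [t.clades(include_root=False) for t in res.optimal_trees]
            target = _with_outgroup(parse_newick("(((A,B),C),(D,E));"),
                                    "OG").clades(include_root=False)
            assert target in keys

    def test_conflicting_inputs_give_multiple_optima(self):
        ts = TreeSet([parse_newick("((A,B),(C,D));", tree_id="x"),
                      parse_newick("((A,C),(B,D));", tree_id="y")])
        m = mrp_encode(ts, outgroup="OG")
        res = search(m, "mrp", restarts=10, seed=2)
        assert len(res.optimal_trees) >= 2

    def test_matches_exhaustive_enumeration_small(self):
        ts = TreeSet([parse_newick("((A,(B,C)),(D,E));", tree_id="1"),
                      parse_newick("(((A,B),C),(D,E));", tree_id="2"),
                      parse_newick("((A,B),((C,D),E));", tree_id="3")])
        m = mrp_encode(ts, outgroup="OG")
        for crit in ("mrp", "mrc"):
            res = search(m, crit, restarts=10, seed=3)
            scores = [_score(_with_outgroup(t, "OG"), m, crit)
                      for t in all_rooted_topologies("ABCDE")]
            exhaustive = min(scores) if crit == "mrp" else max(scores)
            assert res.score == exhaustive

    def test_outgroup_constrained_at_root(self):
        ts = TreeSet([parse_newick("((A,B),(C,OG));", tree_id="t")])
        m = mrp_encode(ts, outgroup="OG")
        res = search(m, "mrp", restarts=5, seed=4)
        for t in res.optimal_trees:
            kids = [set(Tree(c).leaf_labels) for c in t.root.children]
            assert {"OG"} in kids

    def test_determinism(self):
        ts = TreeSet([parse_newick("((A,B),(C,D));", tree_id="x"),
                      parse_newick("((A,C),(B,D));", tree_id="y")])
        m = mrp_encode(ts, outgroup="OG")
        a = search(m, "mrp", restarts=8, seed=7)
        b = search(m, "mrp", restarts=8, seed=7)
        assert [t.to_newick() for t in a.optimal_trees] == \
            [t.to_newick() for t in b.optimal_trees]
        assert a.score == b.score


class TestConsensus:
    def _result(self, newicks, score=0):
        from macrophylo.supertree import SearchResult
        return SearchResult(optimal_trees=[parse_newick(s) for s in newicks],
                            score=score, criterion="mrp", seed=0, restarts=1)

    def test_single_tree_identity(self):
        res = self._result(["(((A,B),C),D);"])
        cons = majority_rule_plus(res)
        assert cons.tree.to_newick() == "(((A,B),C),D);"
        assert all(f == 1.0 for f in cons.clade_frequencies.values())

    def test_majority_clade_included(self):
        res = self._result(["(((A,B),C),D);", "(((A,B),D),C);",
                            "(((A,C),B),D);"])
        cons = majority_rule_plus(res)
        assert frozenset("AB") in cons.clade_frequencies
        assert cons.clade_frequencies[frozenset("AB")] == pytest.approx(2 / 3)

    def test_minority_tie_broken_lexicographically(self):
        # three mutually incompatible resolutions, one vote each; the
        # lexicographically first clade ({A,B} before {A,C} and {B,C})
        # must win the tie
        res = self._result(["((A,B),C);", "((A,C),B);", "((B,C),A);"])
        cons = majority_rule_plus(res)
        assert frozenset("AB") in cons.clade_frequencies

    def test_strict_consensus_is_subset(self):
        newicks = ["((((A,B),C),D),E);", "((((A,B),D),C),E);",
                   "((((A,B),C),E),D);"]
        res = self._result(newicks)
        cons = majority_rule_plus(res)
        trees = [parse_newick(s) for s in newicks]
        strict = set.intersection(
            *(set(t.clades(include_root=False)) for t in trees))
        assert strict <= set(cons.clade_frequencies)

    def test_output_fully_bifurcating(self):
        res = self._result(["((A,B),C,D,E);", "((A,C),B,D,E);"])
        cons = majority_rule_plus(res)
        assert cons.tree.is_bifurcating()

    def test_differing_leaf_sets_rejected(self):
        res = self._result(["((A,B),C);", "((A,B),D);"])
        with pytest.raises(ValueError, match="leaf sets"):
            majority_rule_plus(res)

    def test_tree_from_clades(self):
        t = tree_from_clades("ABCD", [frozenset("AB"), frozenset("ABC")])
        assert t.to_newick() == "(((A,B),C),D);"
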