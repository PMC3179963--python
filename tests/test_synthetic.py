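import numpy as np
import pytest

from macrophylo import (SyntheticScenario, adjust_originations,
                        detect_shifts, extension_summary, gen_fossil_record,
                        gen_input_trees, gen_model_tree, gen_richness,
                        gen_trajectory, majority_rule_plus, mrp_encode,
                        rf_distance, search, v_scores)


class TestScenario:
    def test_invariant_checks(self):
        with pytest.raises(ValueError):
            SyntheticScenario(n_families=2)
        with pytest.raises(ValueError):
            SyntheticScenario(birth_rate=0.01, death_rate=0.02)
        with pytest.raises(ValueError):
            SyntheticScenario(phi=1.5)
        with pytest.raises(ValueError):
            SyntheticScenario(taxon_subsample_fraction=0.0)


class TestModelTree:
    def test_deterministic(self, small_model):
        scenario, model = small_model
        again = gen_model_tree(scenario)
        assert again.tree.to_newick() == model.tree.to_newick()
        assert again.origination == model.origination

    def test_conditioned_on_tip_count(self, small_model):
        scenario, model = small_model
        assert model.tree.n_leaves == scenario.n_families
        assert model.tree.is_bifurcating()

    def test_zero_death_all_extant(self):
        sc = SyntheticScenario(seed=1, n_families=10, death_rate=1e-9)
        model = gen_model_tree(sc)
        assert len(model.extant) == 10

    def test_origination_precedes_extinction(self, small_model):
        _, model = small_model
        for fam in model.origination:
            assert model.origination[fam] >= model.extinction[fam]

    def test_ages_nested_along_tree(self, small_model):
        _, model = small_model
        parents = model.tree.parent_map()
        for node in model.tree.postorder():
            parent = parents[id(node)]
            if parent is not None and not node.is_leaf:
                assert parent.age >= node.age


class TestInputTrees:
    def test_full_sampling_no_noise_reproduces_model(self):
        sc = SyntheticScenario(seed=4, n_families=10,
                               taxon_subsample_fraction=1.0,
                               nni_perturbations=0, n_input_trees=4)
        model = gen_model_tree(sc)
        trees = gen_input_trees(model, sc)
        for t in trees:
            assert rf_distance(t, model.tree) == 0

    def test_subsample_size(self):
        sc = SyntheticScenario(seed=4, n_families=20,
                               taxon_subsample_fraction=0.5,
                               n_input_trees=6)
        model = gen_model_tree(sc)
        for t in gen_input_trees(model, sc):
            assert t.n_leaves == 10

    def test_perturbation_increases_conflict(self):
        base = dict(seed=9, n_families=14, taxon_subsample_fraction=1.0,
                    n_input_trees=20)
        model = gen_model_tree(SyntheticScenario(**base))
        mean_rf = {}
        for k in (0, 2, 6):
            sc = SyntheticScenario(**base, nni_perturbations=k)
            trees = gen_input_trees(model, sc)
            mean_rf[k] = np.mean([rf_distance(t, model.tree)
                                  for t in trees])
        assert mean_rf[0] == 0
        assert mean_rf[2] > 0
        assert mean_rf[6] >= mean_rf[2]


class TestRichness:
    def test_pool_conserved(self, small_model):
        scenario, model = small_model
        table, shift = gen_richness(model, scenario)
        assert shift is None
        assert sum(table.values()) == 170 * len(model.extant)
        assert set(table) == model.extant

    def test_every_family_at_least_one_species(self, small_model):
        scenario, model = small_model
        table, _ = gen_richness(model, scenario)
        assert min(table.values()) >= 1

    def test_implanted_shift_enriches_clade(self):
        sc = SyntheticScenario(seed=6, n_families=12, death_rate=1e-4)
        model = gen_model_tree(sc)
        tree = model.extant_tree
        cm = tree.clade_map()
        target = min((cm[id(k)] for k in tree.root.children), key=len)
        sc.shift_clade = tuple(sorted(target))
        sc.shift_multiplier = 20.0
        table, shift = gen_richness(model, sc)
        assert shift == target
        inside = sum(table[f] for f in target) / len(target)
        outside = sum(table[f] for f in set(table) - target) / \
            (len(table) - len(target))
        assert inside > 5 * outside

    def test_null_rejection_rate_within_alpha(self):
        rej = comp = 0
        for rep in range(100):
            sc = SyntheticScenario(seed=2000 + rep, n_families=16,
                                   death_rate=1e-4)
            model = gen_model_tree(sc)
            table, _ = gen_richness(model, sc)
            rep_ = detect_shifts(model.extant_tree, table)
            rej += sum(c.significant for c in rep_.comparisons)
            comp += len(rep_.comparisons)
        assert rej / comp <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / comp)


class TestFossilRecord:
    def test_extinct_lineage_has_positive_lad(self, small_model):
        scenario, model = small_model
        ranges, _ = gen_fossil_record(model, scenario)
        for fam, r in ranges.items():
            if not r.extant and fam in ranges:
                assert r.lad >= 0
                assert r.fad <= model.origination[fam]

    def test_dense_preservation_recovers_true_originations(self):
        sc = SyntheticScenario(seed=8, n_families=10,
                               preservation_rate=200.0)
        model = gen_model_tree(sc)
        ranges, log = gen_fossil_record(model, sc)
        assert not log
        for fam, r in ranges.items():
            assert model.origination[fam] - r.fad < 0.1

    def test_adjustment_improves_on_raw_record(self):
        # ghost ranges close part of the gap between FAD and the true
        # origination for families whose sister clade left a record
        gaps_raw, gaps_adj = [], []
        for seed in range(10):
            sc = SyntheticScenario(seed=seed)
            model = gen_model_tree(sc)
            ranges, _ = gen_fossil_record(model, sc)
            tree = model.tree.restrict_to(set(ranges))
            adj = adjust_originations(tree, ranges)
            parents = model.tree.parent_map()
            below = model.tree.clade_map()
            for leaf in model.tree.leaves():
                f = leaf.label
                if f not in ranges:
                    continue
                sister = below[id(parents[id(leaf)])] - {f}
                if not (sister & set(ranges)):
                    continue
                gaps_raw.append(model.origination[f] - ranges[f].fad)
                gaps_adj.append(model.origination[f] - adj[f].fad)
                assert adj[f].fad <= model.origination[f] + 1e-9
        assert np.mean(gaps_adj) < np.mean(gaps_raw)


class TestTrajectory:
    def test_noise_free_exponential_is_log_linear(self):
        sc = SyntheticScenario(seed=3, noise_sd=0.0)
        s = gen_trajectory(sc)
        y = np.log1p(s.richness)
        t = s.times_ma[0] - s.times_ma
        slope = np.polyfit(t, y, 1)
        assert np.allclose(np.polyval(slope, t), y, atol=1e-9)
        assert slope[0] == pytest.approx(sc.growth_r)

    def test_trajectory_deterministic(self):
        sc = SyntheticScenario(seed=12)
        a, b = gen_trajectory(sc), gen_trajectory(sc)
        assert np.array_equal(a.richness, b.richness)
        assert np.array_equal(a.times_ma, b.times_ma)

    def test_autocorrelated_noise_depresses_dw(self):
        from macrophylo import akima_resample, durbin_watson, fit_gls_ar1
        dws = []
        for rep in range(20):
            sc = SyntheticScenario(seed=3000 + rep, phi=0.6)
            s = akima_resample(gen_trajectory(sc))
            dws.append(fit_gls_ar1(s, "linear").dw)
        assert np.mean(dws) < 2.0


class TestEndToEnd:
    def test_noise_free_pipeline(self):
        """With full sampling, no topological noise, equal richness and
        dense preservation, every stage must return the exact truth."""
        sc = SyntheticScenario(seed=21, n_families=10, death_rate=1e-4,
                               taxon_subsample_fraction=1.0,
                               nni_perturbations=0, n_input_trees=5,
                               preservation_rate=500.0)
        model = gen_model_tree(sc)
        trees = gen_input_trees(model, sc)

        matrix = mrp_encode(trees, outgroup="OG")
        result = search(matrix, "mrp", restarts=5, seed=1)
        cons = majority_rule_plus(result)
        recovered = cons.tree.restrict_to(model.tree.leaf_set)
        assert rf_distance(recovered, model.tree) == 0

        rep = v_scores(recovered, trees)
        assert rep.tree_v == 1.0

        from macrophylo import RichnessTable
        flat = RichnessTable({f: 100 for f in model.extant})
        shifts = detect_shifts(model.extant_tree, flat)
        assert shifts.significant == []

        ranges, _ = gen_fossil_record(model, sc)
        adj = adjust_originations(model.tree.restrict_to(set(ranges)),
                                  ranges)
        summ = extension_summary(ranges, adj)
        assert summ.max_extension < 0.1   # preservation is near-complete
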