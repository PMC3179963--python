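# macrophylo

Family-level supertrees and fossil-informed diversification analysis.

Old, fossil-rich clades (odonates are the motivating example: dragonflies,
damselflies and their extinct relatives, ~300 Myr of history) pose a
recurring problem: no single dataset covers all families, the fossil
record understates originations, and raw taxic richness curves can
mislead about how diversity accumulated. `macrophylo` implements the full
workflow palaeo-phylogeneticists use to attack this:

1. **Standardize** published trees to one leaf per valid family under a
   user taxonomy (synonyms resolved; paraphyletic families condensed;
   polyphyletic placements removed).
2. **Supertree** construction by matrix representation — parsimony (MRP,
   minimize Fitch length) or compatibility (MRC, maximize characters whose
   1-taxa form a clade) — with all equally optimal trees summarized as a
   fully resolved majority-rule-plus-minority consensus.
3. **Support**: each supertree clade scored against the input trees with
   the V and V+ indices, V = (s−q)/(s+q) on a −1…+1 scale.
4. **Diversification shifts** across all extant sister pairs by the
   Slowinski–Guyer test, p = min(1, 2·N_small/(N_small+N_large−1)), with
   the trickle-down correction (significant nodes pass 2·N_small rootward).
5. **Ghost ranges**: each family's origination pulled back to its sister
   clade's oldest first appearance, adjusted_fad(f) = clade_fad(parent(f)).
6. **Lineage-through-time series** binned on a geological stage table, and
   an exponential-vs-logistic **growth test**: Akima resampling to equal
   spacing, then AR(1)-GLS fits of log(richness+1) on time, linear vs
   quadratic — a significant *negative* quadratic term (deceleration
   toward the present) indicates logistic saturation.
7. A **synthetic-data** module generating every input under known truth
   (birth–death trees, noisy literature-like tree sets, equal-rates-Markov
   richness with implantable shifts, Poisson fossil preservation, AR(1)
   richness trajectories), so every estimator is validated end to end.

The extant-odonate species-richness table and an ICS-derived geological
stage table ship as packaged fixtures; see `docs/methods.md` for models,
assumptions and numerical choices.

## Worked example

```python
import macrophylo as mp

sc = mp.SyntheticScenario(seed=1, n_families=20)
model = mp.gen_model_tree(sc)            # birth–death truth, ages in Ma
trees = mp.gen_input_trees(model, sc)    # 30 noisy partial source trees

matrix = mp.mrp_encode(trees, outgroup="OG")
result = mp.search(matrix, criterion="mrp", restarts=10, seed=1)
consensus = mp.majority_rule_plus(result)
print(f"MRP length {result.score} over {matrix.n_columns} characters; "
      f"{len(result.optimal_trees)} equally optimal tree(s)")

report = mp.v_scores(consensus, trees)
print(f"whole-tree V = {report.tree_v:.3f}, V+ = {report.tree_v_plus:.3f}")

richness, _ = mp.gen_richness(model, sc)
shifts = mp.detect_shifts(model.extant_tree, richness)
print(f"{len(shifts.significant)} significant shifts "
      f"in {len(shifts.comparisons)} sister comparisons")

ranges, _ = mp.gen_fossil_record(model, sc)
tree = model.tree.restrict_to(set(ranges))
adjusted = mp.adjust_originations(tree, ranges)
summary = mp.extension_summary(ranges, adjusted)
print(f"{summary.n_extended} of {len(ranges)} families extended; "
      f"largest ghost range {summary.max_extension:.1f} My "
      f"({summary.max_family})")

series = mp.lineage_series(adjusted, mp.load_timescale(),
                           source="mrp_adjusted").since_first_appearance()
resampled = mp.akima_resample(series)
lin = mp.fit_gls_ar1(resampled, "linear")
quad = mp.fit_gls_ar1(resampled, "quadratic")
print(f"quadratic t = {quad.quad_t:.2f} (df {quad.df}, p = {quad.p:.3f}), "
      f"phi = {quad.phi:.3f}, DW = {quad.dw:.2f}")
print("verdict:", mp.classify_growth(lin, quad))
```

Output:

```
MRP length 270 over 240 characters; 1 equally optimal tree(s)
whole-tree V = 0.793, V+ = 0.793
0 significant shifts in 11 sister comparisons
5 of 13 families extended; largest ghost range 49.7 My (F03)
quadratic t = 1.44 (df 18, p = 0.168), phi = 0.999, DW = 0.42
verdict: exponential_consistent
```

Reading it: 30 half-sampled, NNI-perturbed source trees still pin down a
single optimal supertree whose clades are, on average, strongly supported
(V = 0.79). Richness was generated under the equal-rates null with no
implanted shift, and correctly none is detected. Sparse Poisson
preservation (one find per ~50 lineage-Myr) leaves ghost ranges that the
phylogeny recovers — 5 of 13 preserved families get older originations,
one by ~50 Myr. The adjusted lineage curve shows no significant
deceleration (the quadratic term is positive and non-significant), so
growth is classed exponential-consistent; the tiny Durbin–Watson value is
why the AR(1) error structure is mandatory here.

The same pipeline runs from a shell (`macrophylo simulate | supertree |
support | shifts | ghostranges | ltt | growth`); real studies replace the
simulated directory with their own newick/NEXUS trees, taxonomy TSV,
richness TSV and fossil range TSV in the same formats.

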