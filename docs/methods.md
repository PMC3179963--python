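# Methods

`macrophylo` implements a family-level macroevolutionary workflow of the
kind used for old, fossil-rich insect clades: published phylogenies are
merged into supertrees, tree shape is interrogated for diversification-rate
shifts, the supertree is used to infer ghost ranges in the fossil record,
and the resulting lineage-richness series is tested for exponential versus
logistic growth. This note records the models, the defaults and the design
choices, and what the synthetic validation does and does not establish.

## Taxonomic standardization

Input trees from the literature are heterogeneous: species- or genus-level
tips, synonyms, superseded family concepts. Standardization (i) resolves
every tip through a user taxonomy (valid names, synonyms, member genera)
so each taxon has exactly one name, and (ii) reduces each tree to at most
one leaf per family. A family whose tips are monophyletic is replaced by
one leaf; a family whose tips form a grade around a *single* nested clade
of other taxa is condensed to one leaf sister to that clade (condensation
then has no bearing on relationships among other families); any other
configuration is treated as polyphyletic — uncertain placement — and the
family is removed from that tree. This "single nested interloper" test is
deliberately strict: families whose tips straddle the deepest split of a
source tree, or interleave with several foreign groups, are dropped rather
than condensed at an arbitrary attachment point. Trees left with fewer
than 3 family leaves carry no grouping information and are discarded with
a log entry.

## Supertree construction (MRP / MRC)

Standardized trees are recoded by Baum–Ragan matrix representation: one
binary character per non-root internal node (descendants 1, other taxa in
that source tree 0, taxa absent from the source missing `?`), with the
designated outgroup scored 0 everywhere, anchoring the root. Two optimality
criteria are offered:

* **MRP** — minimize total Fitch parsimony length over the matrix;
* **MRC** — maximize the number of characters whose 1-state taxa form a
  clade of the candidate tree restricted to the character's scored taxa.

Studies of this kind have historically delegated the search to external
parsimony software whose exact settings are rarely recoverable; here the
search is a documented heuristic: greedy stepwise addition in a random taxon order,
then steepest-ascent hill climbing over the NNI neighbourhood with SPR
moves whenever NNI is exhausted, restarted from independent addition
orders. Every complete topology evaluated anywhere that ties the best
score is collected (default cap 1000 distinct topologies; hitting the cap
is reported). The search is exactly reproducible from its seed. On six
taxa it provably matches exhaustive enumeration in the test suite; at the
12-family scale used for validation it recovers the generating tree from
noise-free encodings with perfect score.

Equally optimal trees are summarized as a **majority-rule-plus** consensus:
clades in more than half the optimal trees enter first; remaining clades
are considered in decreasing frequency (ties broken lexicographically on
sorted member labels) and added when compatible. Residual polytomies are
resolved deterministically from the seed, because the diversification
stage requires strict bifurcation; such forced resolutions are reported
with frequency 0.0 so they cannot be mistaken for supported clades.

## Nodal support (V, V+)

Each supertree clade is scored against every input tree after restricting
the clade to the taxa that tree samples: *supports* if the restricted
clade is displayed exactly, *conflicts* if it is incompatible with the
input tree, *permits* if compatible but not displayed (e.g. a polytomy),
*irrelevant* if fewer than two clade members or no outside taxon is
sampled. V = (s−q)/(s+q) over relevant trees; V+ = (s+p−q)/(s+p+q) credits
permitting trees. V is null (and excluded from the whole-tree mean) when
no tree supports or conflicts. "Supports" requires exact display — the
strictest reading; users comparing against published scores computed with
softer variants should expect somewhat lower values here.

## Diversification shifts (Slowinski–Guyer with trickle-down correction)

For extant sister clades of equal age, the equal-rates null makes the
split of their combined species richness N uniform, so
p = min(1, 2·N_small/(N_small+N_large−1)). Every sister pair of the
extant-pruned, bifurcating supertree is tested tips-to-root in one pass,
with α = 0.05 by default and no multiple-testing adjustment (the
convention of this literature). When a node is significant, its clade
passes 2·min(N_a, N_b) rootward instead of its raw sum, eliminating the
trickle-down effect where one strong shift drags every ancestor to
significance. Two behaviours to be aware of, both verified by simulation:

* the substitution can occasionally *create* significance at deep nodes
  under the null (a significant descendant makes its clade look
  artificially poor); the per-node average rejection rate nonetheless
  stays at or below α (measured 0.026–0.045 across scenario families);
* the test itself is symmetric — "upshift" versus "downshift" is
  interpretation. The report labels a significant pair
  `downshift_in_poorer` when the poorer daughter's per-lineage richness
  falls below the tree-wide median, else `upshift_in_richer`; treat the
  label as descriptive.

## Ghost ranges

Sister lineages diverge simultaneously, so each family's origination is
pulled back to the oldest first appearance in its sister clade when that
is older: adjusted_fad(f) = clade_fad(parent(f)). Only the divergence from
the immediate sister is credited to the family; deeper stem segments
belong to ancestral lineage bookkeeping. Last appearances are never
changed; families absent from the tree pass through so the richness curve
can still include them. The adjustment is idempotent and can only push
originations back (dominance), hence the adjusted lineage-through-time
curve is pointwise ≥ the fossil-only curve.

Limitation (quantified in the recovery tests): when a family's *entire*
true sister clade left no fossil record, the pruned tree pairs the family
with an older relative and the implied divergence predates the family's
own stem — the adjustment is then an upper bound on the ancestral
lineage's origination, not the family's. For families whose sister clade
has any record, the adjusted date provably lies between the raw first
appearance and the true origination; in that sense the method is
conservative.

## Lineage series and the growth test

A range table is binned on a geological timescale (a packaged ICS-derived
Carboniferous→Quaternary stage table, 68 stages, overridable). A family
counts in a stage when its [FAD, LAD] interval strictly overlaps the stage
interior — so a FAD on a stage base starts that stage, not the one before;
FADs resolved from stage names should be dated at the stage base (the
conservative choice, configurable upstream). Originations are binned at
the FAD, extinctions (extinct families only) at the LAD, so
Σoriginations − Σextinctions equals the extant count by construction. The
series coordinate is the stage midpoint.

Because stages are unequal, the series is interpolated to the same number
of equally spaced points with an Akima piecewise cubic (endpoints exact;
interpolated richness floored at 0 against mild undershoot). Note that
Akima interpolation is exact on linear data but *not* on quadratics at
unequal spacing — it is a shape-preserving smoother, not a projection.

The growth test fits log(richness+1) against forward-running time
t = −(Ma), by GLS with AR(1) errors: linear (exponential null, since
exponential growth is log-linear) versus quadratic. φ is estimated by
profiled *restricted* maximum likelihood with exact Prais–Winsten
whitening (plain ML is available via `method="ml"`, but at series lengths
near 46 it leaves the quadratic t-test anticonservative — measured size
0.10 versus 0.048 for REML at φ = 0.6). Standard errors use σ̂² =
RSS/(n−k); the quadratic term's two-sided p is read from t with n−k df.
`classify_growth` calls a series logistic-consistent only when the
quadratic term is significant *and* negative — deceleration toward the
present; significant acceleration is still exponential-consistent. The
Durbin–Watson statistic of the uncorrected OLS linear fit is reported as
the diagnostic motivating the AR(1) structure. A variant dropping the
final (extant) point is available (`RichnessSeries.drop_last`).

## Synthetic data: what it emulates, and what it does not

The generators provide every input under known truth:

* **Model tree** — forward birth–death (defaults 0.02/0.008 per
  lineage-Myr) stopped at a total of 34 extant+extinct family lineages,
  giving odonate-like ~300-Myr root ages; extinct tips retained.
* **Input trees** — 30 random leaf subsamples (default 50% of taxa)
  perturbed by NNI moves, emulating partial, mildly conflicting
  literature trees. Real source trees differ systematically (shared
  character data, correlated taxon sampling, soft polytomies); none of
  that correlation structure is modelled.
* **Richness** — a species pool (170 per extant family, the described
  odonate fauna spread over its families) split recursively by a Pólya
  urn: with equal weights each sister split is uniform — *exactly* the
  Slowinski–Guyer null, so the type-I calibration is exact in principle —
  and a weight multiplier on one clade implants a detectable shift. A
  clamp guarantees every family ≥ 1 species; it binds rarely and makes
  extreme splits very slightly less likely than the null prescribes.
* **Fossil record** — homogeneous Poisson preservation (default 0.02
  finds per lineage-Myr) over each terminal lineage's true duration; FAD =
  oldest find. Extinct lineages with no finds are excluded (logged);
  extant families with no finds are kept at FAD 0, like living families
  with no fossil record. Preservation is not time- or
  environment-dependent, and internal (stem) branches shed no fossils.
* **Trajectories** — exponential or logistic mean with stationary AR(1)
  noise, sampled at stage-length-distributed irregular gaps over 300 Myr
  so the Akima step is exercised honestly. The exponential mean is linear
  on the log(richness+1) scale the test fits; defining it as log1p of an
  exponential curve instead would inject real curvature at low richness
  and no test could be calibrated against it.

Passing the synthetic suite therefore shows the estimators are correct
under their own assumptions (uniform splits, homogeneous preservation,
AR(1) noise, tree-shaped input error); it does not validate those
assumptions for any real fauna.

## Validation quantities and problem sizes

`scripts/acceptance.py` recomputes, from scratch at the given seed: the
sister-split oracle agreement (all pairs to N = 500); supertree recovery
(ten 12-family noise-free encodings, MRP and MRC) and exhaustive-search
agreement (three random 6-taxon tree sets, all 10 395 topologies scored);
the noise-free whole-tree V (= 1); shift-test size (500 equal-rates
replicates, 16 families) and power at a 20× implanted shift (500
replicates, detection at the shifted clade's sister comparison);
ghost-range dominance and origination/extinction conservation (5
scenarios); and growth-test size under exponential truth (500
trajectories), logistic detection rate (200 saturated trajectories,
K = 40, r = 0.04/Myr) and mean φ̂ at n = 200 (true φ = 0.6). These sizes
keep the full run around half a minute on one core while leaving
Monte-Carlo error well inside the asserted bands.
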