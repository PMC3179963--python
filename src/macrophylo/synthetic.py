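"""Synthetic data with the statistical structure the pipeline assumes.

Every analysis stage can be exercised, and its estimators validated against
known truth, without any external data:

* a birth–death model tree over "families" with true node ages, conditioned
  on a total (extant + extinct) tip count;
* noisy input-tree sets — random leaf subsamples of the model tree, each
  perturbed by random NNI moves — emulating a heterogeneous literature
  compilation;
* extant species richness per family generated by equal-rates Markov
  splitting of a species pool down the tree (the exact null of the
  Slowinski–Guyer test), with an optional rate multiplier implanted on one
  clade;
* an incomplete fossil record: per-lineage Poisson preservation over each
  family's true duration, so first appearances postdate true originations;
* richness trajectories with exponential or logistic mean and stationary
  AR(1) noise on the log scale, sampled at stage-like irregular intervals.

All generators are deterministic given the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .diversification import RichnessTable
from .ghosts import FossilRange, FossilRangeTable
from .growth import RichnessSeries, load_timescale
from .taxonomy import TreeSet
from .trees import Node, Tree, random_nni

__all__ = [
    "SyntheticScenario",
    "ModelTree",
    "gen_model_tree",
    "gen_input_trees",
    "gen_richness",
    "gen_fossil_record",
    "gen_trajectory",
]


@dataclass
class SyntheticScenario:
    """Parameters of one simulated study.

    Defaults emulate an odonate-like family-level problem: ~34 family
    lineages spanning ~300 Myr (birth 0.02, death 0.008 per lineage-Myr), a
    species pool of ~170 species per extant family (the described odonate
    fauna spread over its families), a patchy family-level
    fossil record (one find per 50 lineage-Myr), and a literature-like
    input-tree set (30 trees, half the taxa each, one NNI's worth of
    conflict).  Trajectory defaults give gentle exponential growth with the
    strong positive lag-1 autocorrelation seen in real richness series.
    """

    seed: int = 0
    n_families: int = 34
    birth_rate: float = 0.02          # per lineage per Myr
    death_rate: float = 0.008
    shift_clade: tuple[str, ...] | None = None  # leaves whose MRCA shifts
    shift_multiplier: float = 1.0
    preservation_rate: float = 0.02   # fossil finds per lineage-Myr
    n_input_trees: int = 30
    taxon_subsample_fraction: float = 0.5
    nni_perturbations: int = 1
    growth_mode: Literal["exponential", "logistic"] = "exponential"
    growth_r: float = 0.02            # per Myr
    carrying_capacity: float = 40.0   # families (logistic only)
    n0: float = 2.0
    noise_sd: float = 0.15            # sd of AR(1) innovations, log scale
    phi: float = 0.6
    species_pool: int | None = None   # default: 170 per extant family
    n_time_points: int = 46
    time_span: float = 300.0          # Myr covered by a trajectory

    def __post_init__(self):
        if self.n_families < 4:
            raise ValueError("n_families must be >= 4")
        if min(self.birth_rate, self.death_rate,
               self.preservation_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.death_rate >= self.birth_rate:
            raise ValueError(
                "death_rate must be below birth_rate (surviving-clade "
                "conditioning)")
        if not 0 < self.taxon_subsample_fraction <= 1:
            raise ValueError("subsample fraction must be in (0, 1]")
        if not -1 < self.phi < 1:
            raise ValueError("|phi| must be < 1")
        if self.shift_multiplier <= 0:
            raise ValueError("shift multiplier must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class ModelTree:
    """A simulated family tree plus the ground truth the estimators target."""

    tree: Tree                       # node ages in Ma before present
    origination: dict[str, float]    # true stem age per family, Ma
    extinction: dict[str, float]     # tip age per family (0 = extant)
    extant: frozenset[str]

    @property
    def extant_tree(self) -> Tree:
        return self.tree.restrict_to(self.extant)


def gen_model_tree(scenario: SyntheticScenario,
                   max_retries: int = 1000) -> ModelTree:
    """Forward birth–death simulation stopped at ``n_families`` total tips.

    Lineages split at rate ``birth_rate`` and die at ``death_rate``; the
    simulation restarts internally if the whole clade goes extinct before
    reaching the target tip count.  Ages are reported in Ma before the
    final speciation event, at which all surviving lineages are scored
    extant.
    """
    rng = scenario.rng(1)
    b, d = scenario.birth_rate, scenario.death_rate
    target = scenario.n_families
    for _ in range(max_retries):
        root = Node()
        t = 0.0
        stem_time: dict[int, float] = {id(root): 0.0}
        end_time: dict[int, float] = {}
        active: list[Node] = [root]
        n_tips = 1
        while active and n_tips < target:
            total = len(active) * (b + d)
            t += rng.exponential(1.0 / total)
            k = int(rng.integers(0, len(active)))
            node = active.pop(k)
            if rng.random() < b / (b + d):
                left, right = Node(), Node()
                node.children = [left, right]
                node.age = t  # absolute for now; converted below
                stem_time[id(left)] = stem_time[id(right)] = t
                active.extend([left, right])
                n_tips += 1
            else:
                end_time[id(node)] = t
        if n_tips == target and active:
            present = t
            extant_nodes = set(map(id, active))
            tree = Tree(root)
            origination: dict[str, float] = {}
            extinction: dict[str, float] = {}
            extant: set[str] = set()
            width = len(str(target))
            idx = 0
            for node in tree.postorder():
                if not node.is_leaf:
                    node.age = present - node.age
                    continue
                idx += 1
                node.label = f"F{idx:0{width}d}"
                if id(node) in extant_nodes:
                    node.age = 0.0
                    extant.add(node.label)
                else:
                    node.age = present - end_time[id(node)]
                extinction[node.label] = node.age
                origination[node.label] = present - stem_time[id(node)]
            return ModelTree(tree=tree, origination=origination,
                             extinction=extinction,
                             extant=frozenset(extant))
    raise RuntimeError(
        f"clade died out in every one of {max_retries} attempts; "
        "raise birth_rate or lower death_rate")


def gen_input_trees(model: ModelTree, scenario: SyntheticScenario
                    ) -> TreeSet:
    """Noisy literature-like source trees: random leaf subsamples of the
    model tree, each degraded by random NNI moves."""
    rng = scenario.rng(2)
    labels = sorted(model.tree.leaf_set)
    n = len(labels)
    size = max(3, int(np.ceil(scenario.taxon_subsample_fraction * n)))
    out = TreeSet()
    for i in range(scenario.n_input_trees):
        chosen = [labels[j] for j in rng.choice(n, size=size, replace=False)]
        sub = model.tree.restrict_to(chosen)
        sub = random_nni(sub, scenario.nni_perturbations, rng)
        sub.tree_id = f"sim{i + 1}"
        for node in sub.postorder():
            node.age = None
        out.trees.append(sub)
    return out


def gen_richness(model: ModelTree, scenario: SyntheticScenario
                 ) -> tuple[RichnessTable, frozenset[str] | None]:
    """Equal-rates Markov richness over the extant tree.

    The species pool is split recursively at every node by a Pólya-urn
    scheme: both daughters start with one species and each subsequent
    species joins a daughter with probability proportional to its current
    count times its rate weight.  With equal weights the resulting sister
    split is uniform — exactly the Slowinski–Guyer null — and a weight
    multiplier on one clade implants a diversification shift there.
    Returns the table and the shifted clade's extant leaf set (or None).
    """
    rng = scenario.rng(3)
    tree = model.extant_tree
    if not tree.is_bifurcating():
        raise ValueError("extant model tree must be bifurcating")
    pool = scenario.species_pool or 170 * len(model.extant)
    shift: frozenset[str] | None = None
    if scenario.shift_clade is not None:
        shift = frozenset(
            tree.clade_map()[id(tree.mrca(scenario.shift_clade))])
    below = tree.clade_map()
    table: dict[str, int] = {}

    def weight(clade: frozenset[str]) -> float:
        if shift is not None and clade <= shift:
            return scenario.shift_multiplier
        return 1.0

    def split(node: Node, n: int) -> None:
        clade = below[id(node)]
        if node.is_leaf:
            table[node.label] = n
            return
        a, b = node.children
        la, lb = len(below[id(a)]), len(below[id(b)])
        wa, wb = weight(below[id(a)]), weight(below[id(b)])
        ka, kb = 1, 1
        for _ in range(n - 2):
            pa = ka * wa / (ka * wa + kb * wb)
            if rng.random() < pa:
                ka += 1
            else:
                kb += 1
        # each daughter needs at least one species per extant family
        ka = min(max(ka, la), n - lb)
        split(a, ka)
        split(b, n - ka)

    if pool < tree.n_leaves:
        raise ValueError("species pool smaller than family count")
    split(tree.root, pool)
    return RichnessTable(table), shift


def gen_fossil_record(model: ModelTree, scenario: SyntheticScenario
                      ) -> tuple[FossilRangeTable, list[str]]:
    """Poisson preservation of each family lineage.

    Finds accrue at ``preservation_rate`` per lineage-Myr over the true
    duration (stem age to extinction/present); the FAD is the oldest find
    and, for extinct families, the LAD the youngest.  Extinct lineages with
    no finds leave no record and are excluded (logged); extant families
    with no finds are retained with FAD 0 — known only from the living
    fauna, like several real families.
    """
    if scenario.preservation_rate <= 0:
        raise ValueError("preservation_rate must be positive")
    rng = scenario.rng(4)
    table = FossilRangeTable()
    log: list[str] = []
    for fam in sorted(model.origination):
        start = model.origination[fam]       # older bound, Ma
        end = model.extinction[fam]          # younger bound, Ma
        duration = start - end
        extant = fam in model.extant
        n_finds = rng.poisson(scenario.preservation_rate * duration)
        if n_finds == 0:
            if extant:
                table[fam] = FossilRange(0.0, 0.0, True)
            else:
                log.append(f"{fam}: extinct and unsampled, excluded")
            continue
        finds = end + duration * rng.random(n_finds)
        fad = float(finds.max())
        lad = 0.0 if extant else float(finds.min())
        table[fam] = FossilRange(fad, lad, extant)
    return table, log


def gen_trajectory(scenario: SyntheticScenario) -> RichnessSeries:
    """A richness trajectory with known growth law and AR(1) log-noise.

    Sampling times are irregular: successive gaps are stage durations drawn
    from the packaged geological timescale, rescaled to ``time_span``, so
    the Akima resampling step is exercised honestly.
    """
    rng = scenario.rng(5)
    n = scenario.n_time_points
    durations = np.array([s.duration for s in load_timescale().stages])
    gaps = durations[rng.integers(0, len(durations), size=n - 1)]
    times_fwd = np.concatenate([[0.0], np.cumsum(gaps)])
    times_fwd *= scenario.time_span / times_fwd[-1]
    # The mean is defined on the log(richness + 1) scale the growth test
    # fits, so "exponential" mode is exactly the linear null of that test
    # (at richness >> 1 this is indistinguishable from log-scale growth).
    if scenario.growth_mode == "exponential":
        y = np.log1p(scenario.n0) + scenario.growth_r * times_fwd
    elif scenario.growth_mode == "logistic":
        k = scenario.carrying_capacity
        c = k / scenario.n0 - 1.0
        y = np.log1p(k / (1.0 + c * np.exp(-scenario.growth_r * times_fwd)))
    else:
        raise ValueError(f"unknown growth mode {scenario.growth_mode!r}")
    if scenario.noise_sd > 0:
        e = np.empty(n)
        e[0] = rng.normal(0.0, scenario.noise_sd /
                          np.sqrt(1 - scenario.phi ** 2))
        for i in range(1, n):
            e[i] = scenario.phi * e[i - 1] + rng.normal(
                0.0, scenario.noise_sd)
        y = y + e
    richness = np.expm1(y)
    times_ma = times_fwd[-1] - times_fwd
    return RichnessSeries(times_ma, np.clip(richness, 0.0, None),
                          source="synthetic")
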