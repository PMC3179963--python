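import pytest

from macrophylo import SyntheticScenario, gen_model_tree
from macrophylo.trees import Tree


def relabel(tree: Tree, mapping: dict[str, str]) -> Tree:
    """Rename leaves of a hand-built tree (duplicates allowed)."""
    t = tree.copy()
    for leaf in t.leaves():
        leaf.label = mapping[leaf.label]
    return t


@pytest.fixture(scope="session")
def small_model():
    """A 12-family birth-death model tree shared across tests."""
    scenario = SyntheticScenario(seed=42, n_families=12)
    return scenario, gen_model_tree(scenario)
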