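import numpy as np
import pytest

from snpinet import (
    CohortSpec,
    SpeciesTree,
    default_species_tree,
    load_cohort,
    simulate_cohort,
    simulate_interaction_history,
)
from snpinet.trees import TreeNode


@pytest.fixture(scope="session")
def tree() -> SpeciesTree:
    return default_species_tree()


@pytest.fixture(scope="session")
def cohort_sim():
    """Noise-free synthetic cohort: 10 planted focal-unique missense
    genes, 50 decoys cycling the four violation types."""
    return simulate_cohort(CohortSpec(rng_seed=1))


@pytest.fixture(scope="session")
def cohort_dir(cohort_sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    cohort_sim.write(out)
    return out


@pytest.fixture(scope="session")
def cohort_bundle(cohort_dir):
    return load_cohort(cohort_dir)


@pytest.fixture(scope="session")
def history_sim():
    """Interaction history with a 10x gain excess planted on the dog
    terminal branch for a quarter of 2,000 pairs."""
    return simulate_interaction_history(
        n_pairs=2000, excess_factor=10.0, planted_gain_branch="dog", rng_seed=1
    )


def random_binary_tree(rng: np.random.Generator, n_tips: int) -> SpeciesTree:
    """Random rooted binary tree over tips t0..t{n-1}."""
    nodes = [TreeNode(name=f"t{i}") for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(name="")
        parent.children = [left, right]
        left.parent = parent
        right.parent = parent
        nodes.append(parent)
    return SpeciesTree(nodes[0])


def random_tip_states(
    rng: np.random.Generator, tree: SpeciesTree, p_unknown: float = 0.2
) -> dict[str, str]:
    """Random present/absent/unknown states with >= 1 known tip."""
    tips = tree.tip_names()
    while True:
        states = {}
        for t in tips:
            r = rng.random()
            if r < p_unknown:
                states[t] = "unknown"
            elif r < p_unknown + (1 - p_unknown) / 2:
                states[t] = "absent"
            else:
                states[t] = "present"
        if any(s != "unknown" for s in states.values()):
            return states
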