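import numpy as np
import pytest

from katzncp.datasets import (
    AssociationMatrix,
    DiseaseDagForest,
    SyntheticConfig,
    generate_synthetic,
)


@pytest.fixture
def diamond_forest() -> DiseaseDagForest:
    """Disease X with a diamond of ancestors: a -> {b, c} -> X."""
    forest = DiseaseDagForest()
    forest.add_disease("X", [("a", "b"), ("a", "c"), ("b", "X"), ("c", "X")])
    return forest


@pytest.fixture
def chain_pair_forest() -> DiseaseDagForest:
    """Two diseases sharing the single ancestor t1 (chains t1->X, t1->Y)."""
    forest = DiseaseDagForest()
    forest.add_disease("X", [("t1", "X")])
    forest.add_disease("Y", [("t1", "Y")])
    return forest


@pytest.fixture
def small_synthetic():
    """Deterministic 20x12 synthetic instance used by several suites."""
    config = SyntheticConfig(n_mirnas=20, n_diseases=12, density=0.15,
                             dag_depth=3, shared_ancestor_pool=10, seed=11)
    return generate_synthetic(config)


@pytest.fixture
def micro_md() -> AssociationMatrix:
    """3 miRNAs x 2 diseases with every row and column populated."""
    values = np.array([[1, 0], [1, 1], [0, 1]], dtype=bool)
    return AssociationMatrix(values, ["m1", "m2", "m3"], ["dX", "dY"])


@pytest.fixture
def micro_forest(chain_pair_forest) -> DiseaseDagForest:
    forest = DiseaseDagForest()
    forest.add_disease("dX", [("t1", "dX")])
    forest.add_disease("dY", [("t1", "dY")])
    return forest


def random_forest(rng: np.random.Generator, n_diseases: int, max_nodes: int) -> DiseaseDagForest:
    """Random small ancestor forest (chains and diamonds) for oracle sweeps."""
    forest = DiseaseDagForest()
    pool = [f"t{k}" for k in range(max_nodes + 2)]
    for j in range(n_diseases):
        d = f"d{j}"
        n_anc = int(rng.integers(0, max_nodes))
        ancestors = list(rng.choice(pool, size=n_anc, replace=False))
        edges = []
        nodes = [d]
        for a in ancestors:
            # attach each ancestor as parent of 1-2 existing nodes: yields
            # chains, forks and diamonds while keeping the disease the sink
            n_children = int(rng.integers(1, min(2, len(nodes)) + 1))
            children = rng.choice(len(nodes), size=n_children, replace=False)
            edges.extend((a, nodes[c]) for c in children)
            nodes.append(a)
        forest.add_disease(d, edges)
    forest.validate()
    return forest
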