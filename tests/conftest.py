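import numpy as np
import pytest

import macropath as mp

# The four-model mammalian extinction-risk example used throughout the docs:
# brain size (Br), body size (B), population density (P), litter size (L),
# gestation period (G), weaning age (W) and red-list status (Status).
COMMON = ["Br~B", "P~B", "L~B+G", "W~G", "Status~P+L+G+W+B"]
MODELS = {
    "null": [],
    "direct": ["Status~Br"],
    "indirect": ["L~Br", "G~Br", "W~Br"],
    "both": ["Status~Br", "L~Br", "G~Br", "W~Br"],
}


@pytest.fixture(scope="session")
def mammal_models():
    return mp.parse_model_set(MODELS, common=COMMON)


@pytest.fixture(scope="session")
def balanced_tree():
    return mp.parse_newick("((A:1,B:1):1,C:2);")


def star_tree(n: int) -> mp.Phylogeny:
    return mp.parse_newick("(" + ",".join(f"s{i}:1" for i in range(n)) + ");")


def random_dag(rng: np.random.Generator, v: int, p_edge: float = 0.4) -> mp.CausalDAG:
    """Random DAG: edges only forward along a shuffled vertex order."""
    names = [f"v{i}" for i in range(v)]
    order = list(rng.permutation(names))
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(names)
    for i in range(v):
        for j in range(i + 1, v):
            if rng.random() < p_edge:
                g.add_edge(order[i], order[j])
    return mp.CausalDAG(g, tuple(names))


@pytest.fixture(scope="session")
def chain_fit_data():
    """One simulated chain A->B (beta=1, lambda=1, n=200) plus its tree."""
    dag = mp.CausalDAG.from_formulas(["B~A"])
    tree = mp.simulate_tree(200, seed=11)
    spec = mp.SimulationSpec(
        tree_size=200, dag=dag, path_coefficients={("A", "B"): 1.0},
        residual_sd={"A": 1.0, "B": 0.5}, lambda_true=1.0, seed=12,
    )
    data = mp.simulate_dag_traits(spec, tree, standardize=False)
    return dag, tree, data
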