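"""Synthetic phylogenies and trait data with the structure PPA assumes.

Traits are generated vertex by vertex in topological order of a causal DAG:

    child = Σ_parents β · parent + ε ,   ε ~ MVN(0, σ² · V_λ)

where V_λ is the tree's shared-path-length matrix with Pagel's λ applied to
its off-diagonal.  Path coefficients are interpreted on the standardized
scale: generated columns are rescaled to unit variance before being used as
parents, and the returned table is standardized, so a simulated β is
directly comparable to a fitted standardized coefficient when the residual
scale is chosen to keep child variances near one (e.g. σ = sqrt(1 - Σβ²)
for uncorrelated parents).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import linalg

from .dag import CausalDAG, causal_order
from .trees import Phylogeny, lambda_transform, parse_newick, phylo_covariance

__all__ = [
    "SimulationSpec",
    "simulate_tree",
    "simulate_dag_traits",
    "binarize",
    "load_simulation_spec",
]


@dataclass
class SimulationSpec:
    """Everything needed to generate one synthetic tree + trait table."""

    tree_size: int
    dag: CausalDAG
    path_coefficients: dict[tuple[str, str], float]
    residual_sd: dict[str, float] = field(default_factory=dict)
    lambda_true: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        declared = set(self.path_coefficients)
        edges = set(self.dag.graph.edges)
        if declared != edges:
            raise ValueError(
                "path_coefficients must cover exactly the DAG's edges; "
                f"missing {sorted(edges - declared)}, "
                f"extra {sorted(declared - edges)}"
            )
        for v, sd in self.residual_sd.items():
            if sd <= 0:
                raise ValueError(f"residual_sd[{v!r}] must be positive")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must lie in [0, 1]")

    def sd(self, vertex: str) -> float:
        return self.residual_sd.get(vertex, 1.0)


def simulate_tree(n: int, seed: int = 0) -> Phylogeny:
    """Random Yule (pure-birth) tree with ``n`` tips labelled t1..tn.

    Lineages split at unit rate; each split picks a uniform extant lineage.
    Branch lengths are strictly positive and the tree is ultrametric.
    """
    if n < 2:
        raise ValueError("a tree needs at least 2 tips")
    return _simulate_tree_nodes(n, np.random.default_rng(seed))


class _Node:
    __slots__ = ("children", "length", "label")

    def __init__(self) -> None:
        self.children: list["_Node"] = []
        self.length = 0.0
        self.label = ""

    def newick(self) -> str:
        if not self.children:
            return f"{self.label}:{self.length:.10f}"
        inner = ",".join(c.newick() for c in self.children)
        return f"({inner}):{self.length:.10f}"


def _simulate_tree_nodes(n: int, rng: np.random.Generator) -> Phylogeny:
    root = _Node()
    left, right = _Node(), _Node()
    root.children = [left, right]
    active = [left, right]
    t = 0.0
    born = {id(left): 0.0, id(right): 0.0}
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        node = active[i]
        node.length = t - born.pop(id(node))
        a, b = _Node(), _Node()
        node.children = [a, b]
        born[id(a)] = t
        born[id(b)] = t
        active[i] = a
        active.append(b)
    k = len(active)
    t += rng.exponential(1.0 / k)
    for i, node in enumerate(active, start=1):
        node.length = t - born[id(node)]
        node.label = f"t{i}"
    text = f"({root.children[0].newick()},{root.children[1].newick()});"
    return parse_newick(text)


def simulate_dag_traits(
    spec: SimulationSpec, tree: Phylogeny, standardize: bool = True
) -> pd.DataFrame:
    """Simulate a trait table under a causal DAG on a phylogeny.

    Residuals are drawn through a Cholesky factor of the λ-transformed
    covariance; vertices are processed in topological order.  With
    ``standardize=True`` (default) the returned table is rescaled to
    zero-mean, unit-variance columns, matching the scale on which path
    coefficients are reported; pass ``standardize=False`` to keep the
    generated scale (e.g. when checking the generator's covariance
    structure, or estimator calibration, where rescaling by noisy realized
    standard deviations would distort the target).
    """
    rng = np.random.default_rng(spec.seed)
    V = lambda_transform(phylo_covariance(tree), spec.lambda_true)
    n = len(V.labels)
    L = linalg.cholesky(V.matrix + 1e-12 * np.eye(n), lower=True)
    columns: dict[str, np.ndarray] = {}
    for vertex in causal_order(spec.dag):
        resid = spec.sd(vertex) * (L @ rng.standard_normal(n))
        value = resid.copy()
        for parent in spec.dag.parents(vertex):
            beta = spec.path_coefficients[(parent, vertex)]
            value = value + beta * columns[parent]
        columns[vertex] = value
    table = pd.DataFrame(columns, index=V.labels)
    table.index.name = "species"
    if standardize:
        table = (table - table.mean()) / table.std(ddof=1)
    return table


def binarize(
    column: pd.Series, threshold: float, labels: tuple[str, str] = ("small", "large")
) -> pd.Series:
    """Dichotomize a continuous column at a threshold.

    Values below the threshold get ``labels[0]``, the rest ``labels[1]``;
    the threshold must fall strictly inside the observed range so both
    levels occur.
    """
    values = column.astype(float)
    if not (values.min() < threshold <= values.max()):
        raise ValueError(
            f"threshold {threshold} leaves an empty level "
            f"(observed range [{values.min()}, {values.max()}])"
        )
    return pd.Series(
        np.where(values < threshold, labels[0], labels[1]),
        index=column.index,
        name=column.name,
    )


def load_simulation_spec(path: str) -> SimulationSpec:
    """Read a SimulationSpec from YAML/JSON.

    Structure: ``{tree_size, model: [formula, ...], coefficients:
    {"parent->child": beta}, residual_sd: {vertex: sd}, lambda: .., seed: ..}``
    """
    with open(path) as fh:
        config = yaml.safe_load(fh)
    dag = CausalDAG.from_formulas(config["model"])
    coefficients = {}
    for key, beta in (config.get("coefficients") or {}).items():
        parent, _, child = key.partition("->")
        coefficients[(parent.strip(), child.strip())] = float(beta)
    return SimulationSpec(
        tree_size=int(config["tree_size"]),
        dag=dag,
        path_coefficients=coefficients,
        residual_sd={k: float(v) for k, v in (config.get("residual_sd") or {}).items()},
        lambda_true=float(config.get("lambda", 1.0)),
        seed=int(config.get("seed", 0)),
    )
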