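"""Causal model sets and d-separation basis sets.

A causal hypothesis is a directed acyclic graph (DAG) over named trait
variables.  Each missing edge implies a conditional independence: for every
non-adjacent pair (x, y) the model claims x ⊥ y given the union of the two
vertices' parents (Shipley's basis set).  Rendered as a regression formula,
the claim for the pair (x, y) reads ``dep ~ cond1 + ... + condm + focal``
where ``dep`` is the pair member later in the causal order, ``focal`` is the
other one, and the partial coefficient of ``focal`` is the quantity tested.

The causal order is a deterministic topological order.  When several models
are analysed together, a single *consensus* order — derived from the union of
all models' edges — is used for every model, so that shared claims render
identically and are fitted only once.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import yaml

__all__ = [
    "CausalDAG",
    "ModelSet",
    "DSepStatement",
    "parse_formula",
    "parse_model_set",
    "causal_order",
    "consensus_order",
    "topological_order",
    "basis_set",
    "dedupe_statements",
    "parameter_count",
    "dag_to_dot",
    "load_model_set",
]


class FormulaError(ValueError):
    """Raised when a path formula or model set is malformed."""


class CycleError(ValueError):
    """Raised when declared paths form a directed cycle."""


def parse_formula(formula: str) -> list[tuple[str, str]]:
    """Parse one ``"child ~ parent1 + parent2"`` path formula.

    Returns the list of (parent, child) edges declared by the formula.
    """
    if formula.count("~") != 1:
        raise FormulaError(
            f"formula {formula!r} must contain exactly one '~' "
            "(child ~ parent1 + parent2)"
        )
    lhs, rhs = formula.split("~")
    child = lhs.strip()
    parents = [p.strip() for p in rhs.split("+")]
    if not child or any(not p for p in parents):
        raise FormulaError(f"formula {formula!r} has an empty variable name")
    edges = []
    for parent in parents:
        if parent == child:
            raise FormulaError(f"self-loop {child!r} ~ {parent!r} is not allowed")
        edges.append((parent, child))
    return edges


@dataclass
class CausalDAG:
    """Directed acyclic graph over trait variables.

    ``declaration`` preserves the order in which variables were first
    mentioned; it seeds the deterministic causal order used to pick the
    dependent variable of each independence claim.
    """

    graph: nx.DiGraph
    declaration: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = [v for v in self.graph.nodes if v not in self.declaration]
        if missing:
            self.declaration = self.declaration + tuple(sorted(missing))
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            path = " -> ".join([e[0] for e in cycle] + [cycle[0][0]])
            raise CycleError(f"declared paths form a cycle: {path}")

    @classmethod
    def from_formulas(
        cls, formulas: Iterable[str], extra_vertices: Iterable[str] = ()
    ) -> "CausalDAG":
        graph = nx.DiGraph()
        declaration: list[str] = []

        def declare(v: str) -> None:
            if v not in graph:
                graph.add_node(v)
                declaration.append(v)

        for formula in formulas:
            for parent, child in parse_formula(formula):
                declare(child)
                declare(parent)
                if graph.has_edge(parent, child):
                    raise FormulaError(
                        f"duplicate path {child} ~ {parent} in model definition"
                    )
                graph.add_edge(parent, child)
        for v in extra_vertices:
            declare(v)
        if graph.number_of_nodes() == 0:
            raise FormulaError("model defines no variables")
        return cls(graph, tuple(declaration))

    @property
    def vertices(self) -> tuple[str, ...]:
        return self.declaration

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    @property
    def v(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def e(self) -> int:
        return self.graph.number_of_edges()

    def parents(self, vertex: str) -> list[str]:
        order = {name: i for i, name in enumerate(self.declaration)}
        return sorted(self.graph.predecessors(vertex), key=order.__getitem__)

    def with_declaration(self, declaration: Sequence[str]) -> "CausalDAG":
        """Same graph, different declaration order (vertex superset allowed)."""
        graph = self.graph.copy()
        graph.add_nodes_from(declaration)
        return CausalDAG(graph, tuple(declaration))


def parameter_count(dag: CausalDAG) -> int:
    """Number of estimated parameters q = edges + vertices.

    Each edge contributes a path coefficient; each vertex an intercept /
    residual term.  q enters the small-sample penalty of the CICc.
    """
    return dag.e + dag.v


def causal_order(dag: CausalDAG) -> list[str]:
    """Deterministic topological order used to orient independence claims.

    Kahn's algorithm run with a stack: after removing a vertex, newly freed
    children are visited depth-first, preferring the variable declared
    earliest.  This keeps causally downstream variables late in the order
    (sinks such as an extinction-risk status end up last) and is stable under
    reformatting of the formula list.
    """
    pos = {v: i for i, v in enumerate(dag.declaration)}
    indeg = {v: dag.graph.in_degree(v) for v in dag.graph}
    stack = sorted((v for v in dag.graph if indeg[v] == 0),
                   key=pos.__getitem__, reverse=True)
    out: list[str] = []
    while stack:
        v = stack.pop()
        out.append(v)
        freed = []
        for child in dag.graph.successors(v):
            indeg[child] -= 1
            if indeg[child] == 0:
                freed.append(child)
        stack.extend(sorted(freed, key=pos.__getitem__, reverse=True))
    return out


def topological_order(dag: CausalDAG) -> list[str]:
    """Topological order with alphabetical tie-breaking.

    General-purpose ordering (independent of declaration order); ties among
    simultaneously available vertices are broken by variable name.
    """
    try:
        return list(nx.lexicographical_topological_sort(dag.graph))
    except nx.NetworkXUnfeasible as exc:  # pragma: no cover - guarded in init
        raise CycleError(str(exc)) from exc


@dataclass(frozen=True)
class DSepStatement:
    """One independence claim of a causal model.

    The claim ``dependent ⊥ focal | conditioning`` is tested by regressing
    ``dependent`` on ``conditioning + (focal,)`` and reading off the partial
    coefficient of ``focal``.  ``conditioning`` keeps its rendering order;
    ``canonical_key`` identifies the exact regression to be fitted.
    """

    dependent: str
    focal: str
    conditioning: tuple[str, ...]

    @property
    def terms(self) -> tuple[str, ...]:
        return self.conditioning + (self.focal,)

    @property
    def canonical_key(self) -> tuple[str, tuple[str, ...]]:
        return (self.dependent, self.terms)

    def render(self) -> str:
        return f"{self.dependent} ~ {' + '.join(self.terms)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def basis_set(dag: CausalDAG, order: Sequence[str] | None = None) -> list[DSepStatement]:
    """Shipley's d-separation basis set of a DAG.

    One claim per non-adjacent vertex pair: the pair member later in the
    causal ``order`` (the DAG's own order by default, a consensus order in
    model-set context) is the regression dependent; the conditioning set is
    the union of both members' parents, rendered in causal order with the
    focal variable last.  |basis set| = v(v-1)/2 - e.
    """
    if order is None:
        order = causal_order(dag)
    rank = {v: i for i, v in enumerate(order)}
    unknown = [v for v in dag.graph if v not in rank]
    if unknown:
        raise ValueError(f"causal order is missing vertices: {unknown}")
    statements = []
    vertices = sorted(dag.graph.nodes, key=rank.__getitem__)
    for x, y in itertools.combinations(vertices, 2):
        if dag.graph.has_edge(x, y) or dag.graph.has_edge(y, x):
            continue
        dep, focal = (y, x) if rank[y] > rank[x] else (x, y)
        cond = (set(dag.graph.predecessors(x)) | set(dag.graph.predecessors(y)))
        cond -= {x, y}
        conditioning = tuple(sorted(cond, key=rank.__getitem__))
        statements.append(DSepStatement(dep, focal, conditioning))
    return statements


@dataclass
class ModelSet:
    """A named collection of causal hypotheses over one shared vertex set."""

    models: dict[str, CausalDAG]
    common_paths: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.models:
            raise FormulaError("model set is empty")
        names = list(self.models)
        base = set(self.models[names[0]].graph.nodes)
        for name in names[1:]:
            if set(self.models[name].graph.nodes) != base:
                raise FormulaError(
                    "all models in a set must share one vertex set; "
                    f"model {name!r} differs"
                )
        for name, dag in self.models.items():
            for parent, child in self.common_paths:
                if not dag.graph.has_edge(parent, child):
                    raise FormulaError(
                        f"model {name!r} is missing common path {child} ~ {parent}"
                    )

    @property
    def names(self) -> list[str]:
        return list(self.models)

    @property
    def variables(self) -> tuple[str, ...]:
        return next(iter(self.models.values())).vertices

    def union_dag(self) -> CausalDAG | None:
        """Union of all models' edges, or None if the union is cyclic."""
        declaration = self.variables
        graph = nx.DiGraph()
        graph.add_nodes_from(declaration)
        for dag in self.models.values():
            graph.add_edges_from(dag.graph.edges)
        if not nx.is_directed_acyclic_graph(graph):
            return None
        return CausalDAG(graph, declaration)


def parse_model_set(
    model_formulas: Mapping[str, Sequence[str]],
    common: Sequence[str] = (),
) -> ModelSet:
    """Build a :class:`ModelSet` from per-model path formulas.

    Each model's DAG is its own paths plus the ``common`` paths; the vertex
    set is the union over every formula in the whole set, so statement counts
    (k) and parameter counts (q) are comparable across models.
    """
    if not model_formulas:
        raise FormulaError("no models given")
    # Global declaration order: common paths first, then models in given order.
    declaration: list[str] = []

    def declare(v: str) -> None:
        if v not in declaration:
            declaration.append(v)

    for formula in common:
        for parent, child in parse_formula(formula):
            declare(child)
            declare(parent)
    for formulas in model_formulas.values():
        for formula in formulas:
            for parent, child in parse_formula(formula):
                declare(child)
                declare(parent)
    if not declaration:
        raise FormulaError("model set defines no variables")

    common_edges = [e for f in common for e in parse_formula(f)]
    models: dict[str, CausalDAG] = {}
    for name, formulas in model_formulas.items():
        if not str(name):
            raise FormulaError("model names must be non-empty")
        dag = CausalDAG.from_formulas(
            list(formulas) + list(common), extra_vertices=declaration
        )
        models[name] = dag.with_declaration(declaration)
    return ModelSet(models, common_edges)


def consensus_order(ms: ModelSet) -> list[str]:
    """One causal order consistent with every model in the set.

    Uses the union of all models' edges when acyclic.  When models disagree
    on edge direction (cyclic union), falls back to averaging each vertex's
    rank across the per-model causal orders, breaking ties alphabetically.
    """
    union = ms.union_dag()
    if union is not None:
        return causal_order(union)
    ranks = {v: 0.0 for v in ms.variables}
    for dag in ms.models.values():
        for i, v in enumerate(causal_order(dag)):
            ranks[v] += i
    return sorted(ms.variables, key=lambda v: (ranks[v], v))


def dedupe_statements(
    ms: ModelSet,
) -> tuple[int, dict[tuple[str, tuple[str, ...]], DSepStatement], dict[str, list[DSepStatement]]]:
    """Pool the basis sets of a model set and deduplicate shared regressions.

    The dependent/focal orientation of every claim follows the consensus
    order, but the conditioning variables are rendered in each model's own
    causal order; two statements are the same regression exactly when their
    rendered term sequences coincide.  Returns ``(total, unique, per_model)``
    where ``total`` sums the per-model statement counts and ``unique`` maps
    canonical keys to statements.
    """
    order = consensus_order(ms)
    per_model: dict[str, list[DSepStatement]] = {}
    unique: dict[tuple[str, tuple[str, ...]], DSepStatement] = {}
    total = 0
    for name, dag in ms.models.items():
        own_rank = {v: i for i, v in enumerate(causal_order(dag))}
        statements = []
        for stmt in basis_set(dag, order):
            conditioning = tuple(sorted(stmt.conditioning, key=own_rank.__getitem__))
            stmt = DSepStatement(stmt.dependent, stmt.focal, conditioning)
            statements.append(stmt)
            unique.setdefault(stmt.canonical_key, stmt)
        per_model[name] = statements
        total += len(statements)
    return total, unique, per_model


def dag_to_dot(dag: CausalDAG, name: str = "model",
               coefficients: Mapping[tuple[str, str], float] | None = None) -> str:
    """Render a DAG as Graphviz DOT, optionally annotating edges with β."""
    lines = [f'digraph "{name}" {{']
    for v in dag.declaration:
        lines.append(f'  "{v}";')
    for parent, child in dag.graph.edges:
        attrs = ""
        if coefficients is not None and (parent, child) in coefficients:
            beta = coefficients[(parent, child)]
            width = 0.5 + 4.0 * min(abs(beta), 1.0)
            color = "black" if beta >= 0 else "red"
            attrs = (f' [label="{beta:.3f}", penwidth={width:.2f}, '
                     f'color={color}]')
        lines.append(f'  "{parent}" -> "{child}"{attrs};')
    lines.append("}")
    return "\n".join(lines) + "\n"


def load_model_set(path: str) -> ModelSet:
    """Read a model set from a YAML/JSON config.

    Expected structure: ``{models: {name: [formula, ...]}, common: [...]}``.
    """
    with open(path) as fh:
        text = fh.read()
    try:
        config = yaml.safe_load(text)
    except yaml.YAMLError:
        config = json.loads(text)
    if not isinstance(config, dict) or "models" not in config:
        raise FormulaError(f"{path}: expected a mapping with a 'models' section")
    models = config["models"]
    common = config.get("common", []) or []
    return parse_model_set({k: v or [] for k, v in models.items()}, common)
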