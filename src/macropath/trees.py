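"""Phylogenies, phylogenetic covariance matrices and trait-table alignment.

Under a Brownian-motion model of trait evolution the expected covariance of a
trait value between two tips equals the branch length shared on their paths
from the root (the depth of their most recent common ancestor).  The n×n
matrix of these shared path lengths, V, is the residual covariance used by
phylogenetic generalized least squares.  Pagel's λ rescales the off-diagonal
entries of V, interpolating between a star phylogeny (λ=0, independent
species) and the untransformed tree (λ=1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("macropath")

__all__ = [
    "Phylogeny",
    "PhyloCovariance",
    "parse_newick",
    "read_newick",
    "phylo_covariance",
    "lambda_transform",
    "align_tip_data",
    "read_trait_table",
]


class NewickError(ValueError):
    """Raised when a Newick string cannot be parsed into a valid phylogeny."""


class AlignmentError(ValueError):
    """Raised when a trait table cannot be matched to a tree's tips."""


@dataclass
class Phylogeny:
    """A rooted tree with branch lengths, thin wrapper over dendropy.

    Tip labels are unique non-empty strings; every non-root edge carries a
    non-negative branch length (zero allowed, e.g. from polytomy resolution).
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        labels = self.tip_labels
        if len(labels) < 2:
            raise NewickError("tree needs at least 2 tips")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise NewickError(f"duplicate tip labels: {dupes}")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:  # root edge; length optional
                continue
            if edge.length is None:
                raise NewickError(
                    "missing branch length on edge above "
                    f"{self._node_name(edge.head_node)!r}"
                )
            if edge.length < 0:
                raise NewickError(
                    "negative branch length on edge above "
                    f"{self._node_name(edge.head_node)!r}"
                )

    @staticmethod
    def _node_name(node: dendropy.Node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        return node.label or "<internal node>"

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def to_newick(self) -> str:
        return (
            self.tree.as_string(schema="newick", suppress_rooting=True).strip()
        )

    def root_to_tip_depths(self) -> dict[str, float]:
        depths = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            edge = node.edge.length or 0.0
            node._depth = (parent._depth if parent is not None else 0.0) + (
                edge if parent is not None else 0.0
            )
            if node.is_leaf():
                depths[node.taxon.label] = node._depth
        return depths

    def prune_to(self, labels: list[str]) -> "Phylogeny":
        """Return a copy restricted to ``labels`` (path lengths preserved)."""
        tree = self.tree.clone(depth=1)
        taxa = [t for t in tree.taxon_namespace if t.label in set(labels)]
        if not taxa:
            raise AlignmentError("no tips left after pruning")
        tree.retain_taxa(taxa)
        return Phylogeny(tree)


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required on non-root edges)."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        pos = ""
        col = getattr(exc, "col_num", None)
        if col is not None:
            pos = f" at character {col}"
        raise NewickError(f"malformed Newick string{pos}: {exc}") from exc
    tree.is_rooted = True
    return Phylogeny(tree)


def read_newick(path: str) -> Phylogeny:
    with open(path) as fh:
        return parse_newick(fh.read())


@dataclass
class PhyloCovariance:
    """Tip-by-tip shared-path-length matrix with an applied Pagel's λ."""

    matrix: np.ndarray
    labels: list[str]
    lam: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("covariance shape does not match label count")
        if not np.allclose(m, m.T):
            raise ValueError("covariance matrix must be symmetric")
        self.matrix = m

    def reorder(self, labels: list[str]) -> "PhyloCovariance":
        idx = [self.labels.index(l) for l in labels]
        return PhyloCovariance(self.matrix[np.ix_(idx, idx)], list(labels), self.lam)


def phylo_covariance(tree: Phylogeny) -> PhyloCovariance:
    """Shared root-to-MRCA path lengths for every pair of tips (λ = 1).

    Diagonal entries are root-to-tip distances.  Computed by one preorder
    pass: each internal node of depth d contributes d to all pairs of tips
    split between its child subtrees.
    """
    labels = tree.tip_labels
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    # assign depths and tip sets bottom-up
    depth: dict[int, float] = {}
    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            depth[id(node)] = 0.0
        else:
            depth[id(node)] = depth[id(parent)] + (node.edge.length or 0.0)
    tipsets: dict[int, list[int]] = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            tipsets[id(node)] = [i]
            V[i, i] = depth[id(node)]
        else:
            children = [tipsets[id(c)] for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            V[i, j] = V[j, i] = d
            tipsets[id(node)] = [i for sub in children for i in sub]
    return PhyloCovariance(V, labels, lam=1.0)


def lambda_transform(V: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Scale off-diagonal entries of V by λ ∈ [0, 1]; diagonal unchanged."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    m = V.matrix * lam
    np.fill_diagonal(m, np.diag(V.matrix))
    return PhyloCovariance(m, list(V.labels), lam=V.lam * lam)


def read_trait_table(path: str, species_column: str | None = None) -> pd.DataFrame:
    """Read a CSV/TSV trait table indexed by species identifiers."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if species_column is None:
        species_column = df.columns[0]
    if species_column not in df.columns:
        raise AlignmentError(f"species column {species_column!r} not in table")
    df = df.set_index(species_column)
    df.index = df.index.astype(str)
    return df


def align_tip_data(
    tree: Phylogeny, data: pd.DataFrame
) -> tuple[Phylogeny, pd.DataFrame]:
    """Match a trait table to a tree: prune to shared species, reorder rows.

    Species names are compared by exact string equality after stripping
    surrounding whitespace.  Dropped tips/rows are logged as warnings.
    Missing values anywhere in the table are an error (statement-wise
    case dropping would make statement sample sizes, and hence CICc values,
    incomparable).
    """
    data = data.copy()
    data.index = data.index.astype(str).str.strip()
    if data.index.duplicated().any():
        dupes = sorted(set(data.index[data.index.duplicated()]))
        raise AlignmentError(f"duplicated species names in trait table: {dupes}")
    tips = [t.strip() for t in tree.tip_labels]
    if len(set(tips)) != len(tips):
        raise AlignmentError("duplicated tip labels after whitespace stripping")
    species = set(data.index)
    tipset = set(tips)
    shared = species & tipset
    if not shared:
        raise AlignmentError("no species shared between tree and trait table")
    if not (species <= tipset or tipset <= species):
        extra_rows = sorted(species - tipset)
        extra_tips = sorted(tipset - species)
        raise AlignmentError(
            "tree tips and table species must nest; unmatched rows "
            f"{extra_rows[:5]} and tips {extra_tips[:5]}"
        )
    dropped_tips = sorted(tipset - shared)
    dropped_rows = sorted(species - shared)
    if dropped_tips:
        logger.warning(
            "pruning %d tree tip(s) absent from the trait table", len(dropped_tips)
        )
        tree = tree.prune_to(sorted(shared))
    if dropped_rows:
        logger.warning(
            "dropping %d table row(s) absent from the tree", len(dropped_rows)
        )
        data = data.loc[sorted(shared)]
    if data.isna().any().any():
        bad = sorted(data.columns[data.isna().any()])
        raise AlignmentError(f"missing values in columns {bad}")
    order = [t.strip() for t in tree.tip_labels]
    data = data.loc[order]
    return tree, data
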