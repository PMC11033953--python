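"""Bipartite graph structure, symmetric degree normalization, subgraph views.

The graph G = (V_r, V_d, E) has snoRNA nodes on one side, disease nodes on the
other, and one edge per known association.  Propagation weights use the
symmetric ("Laplace") normalization 1/(sqrt(deg r) * sqrt(deg d)).

A learned partition assigns every snoRNA to exactly one subgraph; each disease
follows its snoRNA neighbors, so a disease may belong to several subgraphs.
Within subgraph s, a disease d only sees its restricted neighbor set N_ds, and
high-order propagation normalizes by the restricted degree |N_ds| on the
disease side while the snoRNA-side degree |N_r| stays the full-graph degree
(all of r's diseases follow r into its subgraph, so the two coincide).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .data import AssociationTable


@dataclass(frozen=True)
class BipartiteGraph:
    n_snorna: int
    n_disease: int
    edge_snorna: np.ndarray  # shape (n_edges,), snoRNA index per edge
    edge_disease: np.ndarray  # shape (n_edges,), disease index per edge

    def __post_init__(self) -> None:
        if len(self.edge_snorna) != len(self.edge_disease):
            raise ValueError("edge index arrays differ in length")
        if self.n_edges and (
            self.edge_snorna.min() < 0
            or self.edge_snorna.max() >= self.n_snorna
            or self.edge_disease.min() < 0
            or self.edge_disease.max() >= self.n_disease
        ):
            raise ValueError("edge index out of bounds")

    @property
    def n_edges(self) -> int:
        return len(self.edge_snorna)

    @property
    def snorna_degree(self) -> np.ndarray:
        return np.bincount(self.edge_snorna, minlength=self.n_snorna)

    @property
    def disease_degree(self) -> np.ndarray:
        return np.bincount(self.edge_disease, minlength=self.n_disease)

    def nbrs_of_snorna(self, r: int) -> np.ndarray:
        """N_r: diseases adjacent to snoRNA r (sorted)."""
        return np.sort(self.edge_disease[self.edge_snorna == r])

    def nbrs_of_disease(self, d: int) -> np.ndarray:
        """N_d: snoRNAs adjacent to disease d (sorted)."""
        return np.sort(self.edge_snorna[self.edge_disease == d])

    def has_edge(self, r: int, d: int) -> bool:
        return bool(np.any((self.edge_snorna == r) & (self.edge_disease == d)))

    def adjacency(self) -> sp.csr_matrix:
        """Unweighted biadjacency, shape (n_snorna, n_disease)."""
        return sp.csr_matrix(
            (np.ones(self.n_edges), (self.edge_snorna, self.edge_disease)),
            shape=(self.n_snorna, self.n_disease),
        )


def build_graph(
    table: AssociationTable, pairs: Sequence[int] | np.ndarray | None = None
) -> BipartiteGraph:
    """Graph over ALL indexed nodes containing exactly the given pairs as edges.

    ``pairs`` are indices into ``table.pairs``; None means all pairs.  Nodes
    appearing in no selected pair stay in the graph as isolated nodes.
    """
    idx = table.pair_indices()
    if pairs is not None:
        pairs = np.asarray(pairs, dtype=np.int64)
        if pairs.size and (pairs.min() < 0 or pairs.max() >= table.n_pairs):
            raise IndexError("pair index out of bounds")
        idx = idx[pairs]
    return BipartiteGraph(
        n_snorna=table.n_snorna,
        n_disease=table.n_disease,
        edge_snorna=idx[:, 0].copy(),
        edge_disease=idx[:, 1].copy(),
    )


def norm_weight(graph: BipartiteGraph, r: int, d: int) -> float:
    """Symmetric normalization 1/(sqrt|N_r| sqrt|N_d|) for an existing edge."""
    if not graph.has_edge(r, d):
        raise ValueError(f"edge ({r}, {d}) not in graph")
    deg_r = graph.snorna_degree[r]
    deg_d = graph.disease_degree[d]
    assert deg_r > 0 and deg_d > 0
    return 1.0 / (np.sqrt(deg_r) * np.sqrt(deg_d))


def normalized_adjacency(graph: BipartiteGraph) -> sp.csr_matrix:
    """Biadjacency with entries 1/(sqrt|N_r| sqrt|N_d|), shape (N, M).

    Right-multiplying disease embeddings by this matrix performs the
    first-order snoRNA update; the transpose performs the disease update.
    """
    deg_r = graph.snorna_degree.astype(float)
    deg_d = graph.disease_degree.astype(float)
    vals = 1.0 / (
        np.sqrt(deg_r[graph.edge_snorna]) * np.sqrt(deg_d[graph.edge_disease])
    )
    return sp.csr_matrix(
        (vals, (graph.edge_snorna, graph.edge_disease)),
        shape=(graph.n_snorna, graph.n_disease),
    )


@dataclass(frozen=True)
class SubgraphView:
    """Membership and restricted neighbor sets of one subgraph."""

    subgraph_id: int
    member_snornas: np.ndarray
    member_diseases: np.ndarray
    # full-length (n_disease,) restricted degree |N_ds|; zero for non-members
    restricted_degree: np.ndarray
    # edges of this subgraph (snoRNA side, disease side)
    edge_snorna: np.ndarray
    edge_disease: np.ndarray

    def restricted_nbrs_of_disease(self, d: int) -> np.ndarray:
        """N_ds: snoRNAs of this subgraph adjacent to disease d (sorted)."""
        return np.sort(self.edge_snorna[self.edge_disease == d])


@dataclass(frozen=True)
class SubgraphPartition:
    """All views of one assignment plus the sparse operators used by the model.

    ``inter_matrices[s]`` has entries 1/(sqrt|N_ds| sqrt|N_r|) on subgraph-s
    edges (the Eq.-5 operator, disease-by-snoRNA); ``first_order_matrices[s]``
    restricts the FULL-graph normalization 1/(sqrt|N_d| sqrt|N_r|) to
    subgraph-s edges, so the per-subgraph pieces of the first-order disease
    update sum exactly to the full first-order disease embedding.
    """

    views: tuple[SubgraphView, ...]
    assignment: np.ndarray  # snoRNA -> subgraph id snapshot
    inter_matrices: tuple[sp.csr_matrix, ...]
    first_order_matrices: tuple[sp.csr_matrix, ...]

    @property
    def n_subgraphs(self) -> int:
        return len(self.views)


def subgraph_views(graph: BipartiteGraph, snorna_to_sub: np.ndarray, n_subgraphs: int) -> SubgraphPartition:
    """Split the graph by a snoRNA->subgraph assignment.

    Every snoRNA lands in exactly one subgraph together with all its edges, so
    a disease appears in every subgraph that holds one of its neighbors and
    its restricted neighbor sets partition N_d across views.
    """
    snorna_to_sub = np.asarray(snorna_to_sub, dtype=np.int64)
    if len(snorna_to_sub) != graph.n_snorna:
        raise ValueError("assignment must cover all snoRNAs")
    if snorna_to_sub.size and (snorna_to_sub.min() < 0 or snorna_to_sub.max() >= n_subgraphs):
        raise ValueError("subgraph id out of range")

    deg_r_full = graph.snorna_degree.astype(float)
    deg_d_full = graph.disease_degree.astype(float)
    edge_sub = snorna_to_sub[graph.edge_snorna] if graph.n_edges else np.empty(0, dtype=np.int64)

    views: list[SubgraphView] = []
    inter: list[sp.csr_matrix] = []
    first: list[sp.csr_matrix] = []
    shape = (graph.n_disease, graph.n_snorna)
    for s in range(n_subgraphs):
        mask = edge_sub == s
        es, ed = graph.edge_snorna[mask], graph.edge_disease[mask]
        restricted_degree = np.bincount(ed, minlength=graph.n_disease).astype(float)
        views.append(
            SubgraphView(
                subgraph_id=s,
                member_snornas=np.flatnonzero(snorna_to_sub == s),
                member_diseases=np.flatnonzero(restricted_degree > 0),
                restricted_degree=restricted_degree,
                edge_snorna=es,
                edge_disease=ed,
            )
        )
        w_inter = 1.0 / (np.sqrt(restricted_degree[ed]) * np.sqrt(deg_r_full[es]))
        inter.append(sp.csr_matrix((w_inter, (ed, es)), shape=shape))
        w_first = 1.0 / (np.sqrt(deg_d_full[ed]) * np.sqrt(deg_r_full[es]))
        first.append(sp.csr_matrix((w_first, (ed, es)), shape=shape))
    return SubgraphPartition(
        views=tuple(views),
        assignment=snorna_to_sub.copy(),
        inter_matrices=tuple(inter),
        first_order_matrices=tuple(first),
    )


def export_graph_tsv(graph: BipartiteGraph, path: str | Path) -> None:
    """Edge list with the per-edge normalization weight (debug aid)."""
    weights = normalized_adjacency(graph)
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["snorna_index", "disease_index", "norm_weight"])
        for r, d in zip(graph.edge_snorna, graph.edge_disease):
            writer.writerow([int(r), int(d), f"{weights[r, d]:.10g}"])
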