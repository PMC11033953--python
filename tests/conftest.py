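"""Shared fixtures and independent dense reference implementations.

The reference implementations here deliberately avoid the package's sparse
code paths: they build dense matrices and loop over nodes, so they can serve
as oracles for the propagation arithmetic.
"""

from __future__ import annotations

import numpy as np
import pytest

import snolink as sl


def lightgcn_reference(
    e_r0: np.ndarray, e_d0: np.ndarray, edges: list[tuple[int, int]], n_layers: int
) -> tuple[np.ndarray, np.ndarray]:
    """Plain LightGCN on the full (N+M)-node graph, dense matrices only."""
    n, dim = e_r0.shape
    m = e_d0.shape[0]
    adj = np.zeros((n + m, n + m))
    for r, d in edges:
        adj[r, n + d] = adj[n + d, r] = 1.0
    deg = adj.sum(axis=1)
    d_inv = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    a_hat = d_inv[:, None] * adj * d_inv[None, :]
    layers = [np.vstack([e_r0, e_d0])]
    for _ in range(n_layers):
        layers.append(a_hat @ layers[-1])
    final = np.mean(layers, axis=0)
    return final[:n], final[n:]


def subgraph_reference(
    e_r0: np.ndarray,
    e_d0: np.ndarray,
    edges: list[tuple[int, int]],
    assign: np.ndarray,
    n_subgraphs: int,
    n_layers: int,
) -> tuple[np.ndarray, np.ndarray, list[list[np.ndarray]]]:
    """Loop-based dense computation of the subgraph-restricted propagation.

    Layer 1 is the full-graph first-order pass; its subgraph-local disease
    pieces keep full-graph normalization.  Layers >= 2 confine propagation
    within subgraphs and use the restricted disease degree.  Returns final
    snoRNA/disease embeddings and the per-layer subgraph-local disease
    matrices.
    """
    n, dim = e_r0.shape
    m = e_d0.shape[0]
    nbr_r = [[d for (r2, d) in edges if r2 == r] for r in range(n)]
    nbr_d = [[r for (r, d2) in edges if d2 == d] for d in range(m)]
    deg_r = np.array([len(x) for x in nbr_r], dtype=float)
    deg_d = np.array([len(x) for x in nbr_d], dtype=float)
    deg_ds = np.zeros((n_subgraphs, m))
    for d in range(m):
        for r in nbr_d[d]:
            deg_ds[assign[r], d] += 1

    e_r1 = np.zeros_like(e_r0)
    e_d1 = np.zeros_like(e_d0)
    dsub1 = [np.zeros_like(e_d0) for _ in range(n_subgraphs)]
    for r in range(n):
        for d in nbr_r[r]:
            w = 1.0 / np.sqrt(deg_r[r] * deg_d[d])
            e_r1[r] += w * e_d0[d]
            e_d1[d] += w * e_r0[r]
            dsub1[assign[r]][d] += w * e_r0[r]

    er_layers = [e_r0, e_r1]
    ed_layers = [e_d0, e_d1]
    dsub_layers = [dsub1]
    for _ in range(n_layers - 1):
        e_r_prev, dsub_prev = er_layers[-1], dsub_layers[-1]
        e_r_next = np.zeros_like(e_r0)
        dsub_next = [np.zeros_like(e_d0) for _ in range(n_subgraphs)]
        for r in range(n):
            s = assign[r]
            for d in nbr_r[r]:
                e_r_next[r] += dsub_prev[s][d] / np.sqrt(deg_r[r] * deg_ds[s, d])
                dsub_next[s][d] += e_r_prev[r] / np.sqrt(deg_ds[s, d] * deg_r[r])
        er_layers.append(e_r_next)
        ed_layers.append(np.sum(dsub_next, axis=0))
        dsub_layers.append(dsub_next)
    return (
        np.mean(er_layers, axis=0),
        np.mean(ed_layers, axis=0),
        dsub_layers,
    )


def random_bipartite(
    rng: np.random.Generator,
    max_snorna: int = 10,
    max_disease: int = 10,
    p_edge: float = 0.4,
) -> tuple[sl.BipartiteGraph, list[tuple[int, int]]]:
    """Small random bipartite graph with at least one edge."""
    while True:
        n = int(rng.integers(2, max_snorna + 1))
        m = int(rng.integers(2, max_disease + 1))
        cells = rng.random((n, m)) < p_edge
        if cells.any():
            break
    edges = [(int(r), int(d)) for r, d in zip(*np.nonzero(cells))]
    graph = sl.BipartiteGraph(
        n_snorna=n,
        n_disease=m,
        edge_snorna=np.array([e[0] for e in edges]),
        edge_disease=np.array([e[1] for e in edges]),
    )
    return graph, edges


@pytest.fixture(scope="session")
def two_block_data():
    """A clean 2-block planted table used across modules."""
    config = sl.PlantedConfig(
        n_blocks=2, snornas_per_block=10, diseases_per_block=8,
        p_in=0.9, p_out=0.02, seed=11,
    )
    return sl.generate_planted(config)


@pytest.fixture(scope="session")
def trained_two_block(two_block_data):
    """One trained model on the 2-block data (shared; tests must not mutate)."""
    table, labels = two_block_data
    plan = sl.split_pairs(table, 0.8, seed=1)
    graph_train = sl.build_graph(table, plan.train_pairs)
    model_config = sl.ModelConfig(n_subgraphs=2, seed=1)
    train_config = sl.TrainConfig(epochs=400, seed=1)
    fitted = sl.train(model_config, train_config, graph_train)
    return {
        "table": table,
        "labels": labels,
        "plan": plan,
        "graph_train": graph_train,
        "model_config": model_config,
        "fitted": fitted,
    }
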