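"""Propagation model: initialization, each pipeline stage, full forward."""

import numpy as np
import pytest

import snolink as sl
from snolink.data import AssociationTable
from snolink.model import (
    Parameters,
    assign_subgraphs,
    combine_layers,
    forward,
    fuse_features,
    init_embeddings,
    init_parameters,
    load_checkpoint,
    propagate_first_order,
    propagate_high_order,
    save_checkpoint,
    score,
    score_all,
)

from conftest import lightgcn_reference, random_bipartite, subgraph_reference


def small_graph():
    table = AssociationTable.from_pairs(
        [("s0", "d0"), ("s0", "d1"), ("s1", "d1"), ("s2", "d2")]
    )
    return table, sl.build_graph(table)


class TestInit:
    def test_shapes_and_determinism(self):
        state = init_embeddings(3, 2, 4, seed=0)
        assert state.snorna_layers[0].shape == (3, 4)
        assert state.disease_layers[0].shape == (2, 4)
        again = init_embeddings(3, 2, 4, seed=0)
        assert np.array_equal(state.snorna_layers[0], again.snorna_layers[0])

    def test_moments(self):
        state = init_embeddings(1000, 100, 100, seed=1)
        draws = state.snorna_layers[0].ravel()
        se = 0.1 / np.sqrt(draws.size)
        assert abs(draws.mean()) < 3 * se
        assert np.std(draws) == pytest.approx(0.1, rel=0.05)

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            init_embeddings(0, 2, 4, seed=0)


class TestFirstOrder:
    def test_single_edge_copies_neighbor(self):
        table = AssociationTable.from_pairs([("s0", "d0")])
        graph = sl.build_graph(table)
        rng = np.random.default_rng(0)
        e_r0, e_d0 = rng.normal(size=(1, 3)), rng.normal(size=(1, 3))
        e_r1, e_d1 = propagate_first_order(e_r0, e_d0, graph)
        assert np.allclose(e_r1[0], e_d0[0])
        assert np.allclose(e_d1[0], e_r0[0])

    def test_two_neighbor_weights(self):
        # r0~{d0,d1}, r1~{d1}: deg(r0)=2, deg(d0)=1, deg(d1)=2
        table = AssociationTable.from_pairs(
            [("s0", "d0"), ("s0", "d1"), ("s1", "d1")]
        )
        graph = sl.build_graph(table)
        rng = np.random.default_rng(1)
        e_r0, e_d0 = rng.normal(size=(2, 4)), rng.normal(size=(2, 4))
        e_r1, _ = propagate_first_order(e_r0, e_d0, graph)
        expected = e_d0[0] / np.sqrt(2) + e_d0[1] / 2.0
        assert np.allclose(e_r1[0], expected)

    def test_empty_graph_zero(self):
        table = AssociationTable.from_pairs([("s0", "d0")])
        graph = sl.build_graph(table, [])
        e_r1, e_d1 = propagate_first_order(np.ones((1, 2)), np.ones((1, 2)), graph)
        assert not e_r1.any() and not e_d1.any()

    def test_matches_dense_reference(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            graph, edges = random_bipartite(rng)
            e_r0 = rng.normal(size=(graph.n_snorna, 5))
            e_d0 = rng.normal(size=(graph.n_disease, 5))
            e_r1, e_d1 = propagate_first_order(e_r0, e_d0, graph)
            ref_r, ref_d, _ = subgraph_reference(
                e_r0, e_d0, edges, np.zeros(graph.n_snorna, dtype=int), 1, 1
            )
            # reference returns layer-combined; invert the 2-layer average
            assert np.allclose(e_r1, 2 * ref_r - e_r0)
            assert np.allclose(e_d1, 2 * ref_d - e_d0)


class TestGenerator:
    def _params(self, dim=3, hidden=3, n_sub=3):
        return Parameters(
            e_r0=np.zeros((2, dim)),
            e_d0=np.zeros((2, dim)),
            fuse_weight=np.eye(dim),
            fuse_bias=np.zeros(dim),
            mlp1_weight=np.eye(hidden, dim),
            mlp1_bias=np.zeros(hidden),
            mlp2_weight=np.eye(n_sub, hidden),
            mlp2_bias=np.zeros(n_sub),
        )

    def test_fusion_identity_on_nonnegative(self):
        params = self._params()
        e0 = np.array([[1.0, 2.0, 0.0], [0.5, 0.0, 3.0]])
        e1 = np.array([[0.0, 1.0, 1.0], [2.0, 0.0, 0.0]])
        assert np.allclose(fuse_features(e0, e1, params), e0 + e1)

    def test_fusion_leaky_slope_on_negative(self):
        params = self._params()
        e0 = np.array([[-2.0, 1.0, 0.0]])
        e1 = np.zeros((1, 3))
        fused = fuse_features(e0, e1, params, slope=0.01)
        assert fused[0, 0] == pytest.approx(-0.02)
        assert fused[0, 1] == pytest.approx(1.0)

    def test_zero_inputs_zero_fusion(self):
        params = self._params()
        assert not fuse_features(np.zeros((2, 3)), np.zeros((2, 3)), params).any()

    def test_argmax_assignment(self):
        params = self._params()
        fused = np.array([[0.1, 0.9, 0.3], [0.2, 0.1, 0.0]])
        out = assign_subgraphs(fused, params, mode="hard")
        assert out.snorna_to_sub.tolist() == [1, 0]
        assert out.soft_weights is None

    def test_tie_breaks_to_lowest_index(self):
        params = self._params(n_sub=2)
        fused = np.array([[0.5, 0.5, 0.0]])
        out = assign_subgraphs(fused, params, mode="hard")
        assert out.snorna_to_sub.tolist() == [0]

    def test_single_subgraph_all_zero(self):
        params = self._params(n_sub=1)
        fused = np.random.default_rng(0).normal(size=(5, 3))
        out = assign_subgraphs(fused, params, mode="straight_through")
        assert set(out.snorna_to_sub.tolist()) == {0}
        assert np.allclose(out.soft_weights, 1.0)


class TestHighOrder:
    def test_single_subgraph_equals_plain_layer(self):
        rng = np.random.default_rng(3)
        graph, edges = random_bipartite(rng)
        part = sl.subgraph_views(graph, np.zeros(graph.n_snorna, dtype=int), 1)
        e_r = rng.normal(size=(graph.n_snorna, 4))
        e_d = rng.normal(size=(graph.n_disease, 4))
        e_r_next, _, e_d_next = propagate_high_order(e_r, [e_d], part)
        plain_r, plain_d = propagate_first_order(e_r, e_d, graph)
        # single-subgraph restricted degrees equal full degrees
        assert np.allclose(e_r_next, plain_r)
        assert np.allclose(e_d_next, plain_d)

    def test_disconnected_subgraph_isolation(self):
        # two blocks with no shared diseases; perturbation in one block
        # cannot reach the other within a high-order step
        pairs = [("a0", "x0"), ("a1", "x0"), ("b0", "y0"), ("b1", "y0")]
        table = AssociationTable.from_pairs(pairs)
        graph = sl.build_graph(table)
        assign = np.array([0, 0, 1, 1])
        part = sl.subgraph_views(graph, assign, 2)
        rng = np.random.default_rng(4)
        e_r = rng.normal(size=(4, 3))
        d_sub = [rng.normal(size=(2, 3)), rng.normal(size=(2, 3))]
        base_r, base_sub, _ = propagate_high_order(e_r, d_sub, part)
        e_r_pert = e_r.copy()
        e_r_pert[2:] += 100.0  # perturb subgraph-1 snoRNAs
        pert_r, pert_sub, _ = propagate_high_order(e_r_pert, d_sub, part)
        assert np.allclose(base_r[:2], pert_r[:2])
        assert np.allclose(base_sub[0], pert_sub[0])
        assert not np.allclose(base_sub[1], pert_sub[1])

    def test_stale_partition_rejected(self):
        graph = sl.BipartiteGraph(2, 1, np.array([0, 1]), np.array([0, 0]))
        part = sl.subgraph_views(graph, np.array([0, 1]), 2)
        with pytest.raises(ValueError, match="stale"):
            propagate_high_order(
                np.zeros((2, 2)), [np.zeros((1, 2))] * 2, part,
                assignment=np.array([1, 0]),
            )


class TestCombineAndScore:
    def test_mean_of_layers(self):
        layers = [np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]]), np.array([[1.0, 1.0]])]
        assert np.allclose(combine_layers(layers), [[2 / 3, 2 / 3]])

    def test_single_layer_identity(self):
        layer = np.random.default_rng(0).normal(size=(3, 2))
        assert np.allclose(combine_layers([layer]), layer)

    def test_score_examples(self):
        e_r = np.array([[1.0, 2.0]])
        e_d = np.array([[3.0, 4.0], [0.0, 0.0]])
        assert score(e_r, e_d, 0, 0) == pytest.approx(11.0)
        assert score(e_r, e_d, 0, 1) == 0.0

    def test_score_all_matches_elementwise(self):
        rng = np.random.default_rng(1)
        e_r, e_d = rng.normal(size=(4, 3)), rng.normal(size=(5, 3))
        matrix = score_all(e_r, e_d)
        for r in range(4):
            for d in range(5):
                assert matrix[r, d] == pytest.approx(score(e_r, e_d, r, d))


class TestForward:
    def test_lightgcn_degeneration_single_subgraph(self):
        rng = np.random.default_rng(0)
        for trial in range(10):
            graph, edges = random_bipartite(rng)
            config = sl.ModelConfig(
                embed_dim=6, n_layers=3, n_subgraphs=1, seed=trial
            )
            params = init_parameters(graph.n_snorna, graph.n_disease, config)
            result = forward(params, graph, config)
            ref_r, ref_d = lightgcn_reference(params.e_r0, params.e_d0, edges, 3)
            assert np.allclose(result.e_r, ref_r, rtol=1e-6, atol=1e-12)
            assert np.allclose(result.e_d, ref_d, rtol=1e-6, atol=1e-12)

    def test_ablation_flag_matches_reference(self):
        rng = np.random.default_rng(9)
        graph, edges = random_bipartite(rng)
        config = sl.ModelConfig(embed_dim=4, n_layers=2, n_subgraphs=4,
                                ablation_lightgcn=True, seed=0)
        params = init_parameters(graph.n_snorna, graph.n_disease, config)
        result = forward(params, graph, config)
        ref_r, ref_d = lightgcn_reference(params.e_r0, params.e_d0, edges, 2)
        assert np.allclose(result.e_r, ref_r)
        assert np.allclose(result.e_d, ref_d)

    def test_matches_dense_subgraph_reference(self):
        rng = np.random.default_rng(13)
        for trial in range(20):
            graph, edges = random_bipartite(rng)
            config = sl.ModelConfig(embed_dim=4, n_layers=int(rng.integers(2, 5)),
                                    n_subgraphs=int(rng.integers(2, 5)), seed=trial)
            params = init_parameters(graph.n_snorna, graph.n_disease, config)
            result = forward(params, graph, config)
            ref_r, ref_d, _ = subgraph_reference(
                params.e_r0, params.e_d0, edges,
                result.assignment.snorna_to_sub, config.n_subgraphs,
                config.n_layers,
            )
            assert np.allclose(result.e_r, ref_r, atol=1e-10)
            assert np.allclose(result.e_d, ref_d, atol=1e-10)

    def test_disease_sub_layers_sum_to_layers(self):
        rng = np.random.default_rng(2)
        graph, _ = random_bipartite(rng)
        config = sl.ModelConfig(embed_dim=5, n_layers=3, n_subgraphs=3, seed=5)
        params = init_parameters(graph.n_snorna, graph.n_disease, config)
        result = forward(params, graph, config)
        for k in range(1, config.n_layers + 1):
            total = np.sum(result.state.disease_sub_layers[k - 1], axis=0)
            assert np.allclose(total, result.state.disease_layers[k], atol=1e-12)

    def test_forward_deterministic(self):
        rng = np.random.default_rng(6)
        graph, _ = random_bipartite(rng)
        config = sl.ModelConfig(embed_dim=4, seed=3)
        params = init_parameters(graph.n_snorna, graph.n_disease, config)
        a = forward(params, graph, config)
        b = forward(params, graph, config)
        assert np.array_equal(a.e_r, b.e_r)
        assert np.array_equal(a.assignment.snorna_to_sub, b.assignment.snorna_to_sub)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(21)
        graph, edges = random_bipartite(rng)
        config = sl.ModelConfig(embed_dim=4, n_layers=2, n_subgraphs=3, seed=1)
        params = init_parameters(graph.n_snorna, graph.n_disease, config)
        result = forward(params, graph, config)

        perm_r = rng.permutation(graph.n_snorna)
        perm_d = rng.permutation(graph.n_disease)
        inv_r = np.argsort(perm_r)
        inv_d = np.argsort(perm_d)
        graph_p = sl.BipartiteGraph(
            graph.n_snorna, graph.n_disease,
            edge_snorna=inv_r[graph.edge_snorna],
            edge_disease=inv_d[graph.edge_disease],
        )
        params_p = params.copy()
        params_p.e_r0 = params.e_r0[perm_r]
        params_p.e_d0 = params.e_d0[perm_d]
        result_p = forward(params_p, graph_p, config)
        assert np.allclose(result_p.e_r, result.e_r[perm_r], atol=1e-10)
        assert np.allclose(result_p.e_d, result.e_d[perm_d], atol=1e-10)


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        config = sl.ModelConfig(embed_dim=4, seed=2)
        params = init_parameters(3, 2, config)
        path = tmp_path / "model.npz"
        save_checkpoint(path, params, config, seed=2)
        loaded, loaded_config, seed = load_checkpoint(path)
        assert loaded_config == config and seed == 2
        for name in params.names():
            assert np.array_equal(getattr(loaded, name), getattr(params, name))
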