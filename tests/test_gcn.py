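"""Product GCN: slicing, lifting, tangent layers, decoder, training."""

import itertools

import numpy as np
import pytest

from pathcurv import manifolds as mf
from pathcurv.edge_prediction import sample_negatives, split_edges
from pathcurv.euclidean_gcn import build_plain_gcn, fit_plain_gcn
from pathcurv.gcn import (
    Adam,
    GCNHyperparams,
    GCNLayer,
    LayerSpec,
    ProductGCNModel,
    _loss_and_grads,
    _stack_forward,
    decode_edge,
    fermi_dirac,
    lift_to_manifold,
    normalized_adjacency,
    predict_scores,
    riemannian_adam_fit,
    score_pairs,
    slice_embedding,
    tangent_gcn_layer,
)
from pathcurv.graphs import PathwayGraph, generate_synthetic
from pathcurv.manifolds import Component, Signature


class TestSlicing:
    def test_seven_component_signature_yields_fourteens(self):
        sig = Signature.parse(
            "H14_1 x H14_1 x S14_1 x S14_1 x S14_1 x E14 x E14"
        )
        blocks = slice_embedding(np.zeros((5, 100)), sig)
        assert len(blocks) == 7
        assert all(b.shape == (5, 14) for b in blocks)

    def test_single_component_keeps_everything(self):
        blocks = slice_embedding(np.zeros((3, 100)), Signature.parse("E100"))
        assert len(blocks) == 1 and blocks[0].shape == (3, 100)

    def test_even_split_drops_nothing(self):
        blocks = slice_embedding(np.arange(20.0).reshape(2, 10), Signature.parse("H5_1 x E5"))
        assert [b.shape for b in blocks] == [(2, 5), (2, 5)]
        np.testing.assert_array_equal(np.concatenate(blocks, axis=1), np.arange(20.0).reshape(2, 10))

    def test_more_components_than_dims_rejected(self):
        with pytest.raises(ValueError):
            slice_embedding(np.zeros((2, 2)), Signature.parse("E1 x E1 x E1"))


class TestLifting:
    def test_zero_features_land_at_origin(self):
        comp = Component(mf.SPHERICAL, 4, 2.0)
        out = lift_to_manifold(np.zeros((3, 4)), comp)
        np.testing.assert_allclose(out, np.tile(mf.origin(comp), (3, 1)), atol=1e-12)

    def test_euclidean_passthrough(self):
        X = np.arange(6.0).reshape(2, 3)
        assert np.array_equal(lift_to_manifold(X, Component(mf.EUCLIDEAN, 3)), X)

    def test_hyperbolic_closed_form(self):
        out = lift_to_manifold(np.array([[1.0, 0.0]]), Component(mf.HYPERBOLIC, 2, 1.0))
        np.testing.assert_allclose(out[0], [np.cosh(1.0), np.sinh(1.0), 0.0], atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            lift_to_manifold(np.zeros((2, 3)), Component(mf.HYPERBOLIC, 2, 1.0))


class TestTangentLayer:
    def test_identity_on_isolated_node(self):
        comp = Component(mf.HYPERBOLIC, 3, 1.0)
        g = PathwayGraph.from_edges([], extra_nodes=["solo"])
        A = normalized_adjacency(g)
        layer = GCNLayer(LayerSpec(3, 3, comp, use_bias=False), np.eye(3), np.zeros(3))
        p = mf.random_points(comp, 1, np.random.default_rng(0))
        out = tangent_gcn_layer(p, A, layer)
        np.testing.assert_allclose(out, p, atol=1e-9)

    def test_euclidean_reduces_to_standard_gcn_layer(self, triangle):
        comp = Component(mf.EUCLIDEAN, 4)
        A = normalized_adjacency(triangle)
        rng = np.random.default_rng(1)
        W = rng.standard_normal((4, 4))
        b = rng.standard_normal(4)
        X = rng.standard_normal((3, 4))
        layer = GCNLayer(LayerSpec(4, 4, comp, activation="relu"), W, b)
        out = tangent_gcn_layer(X, A, layer)
        np.testing.assert_allclose(out, np.maximum(A @ (X @ W) + b, 0.0), atol=1e-12)

    def test_two_node_average_is_tangent_midpoint(self):
        comp = Component(mf.SPHERICAL, 2, 1.0)
        g = PathwayGraph.from_edges([("a", "b")])
        A = np.full((2, 2), 0.5)  # plain averaging aggregation
        layer = GCNLayer(LayerSpec(2, 2, comp, use_bias=False), np.eye(2), np.zeros(2))
        P = mf.random_points(comp, 2, np.random.default_rng(3))
        out = tangent_gcn_layer(P, A, layer)
        np.testing.assert_allclose(out[0], out[1], atol=1e-9)
        T = mf.log_origin(P, comp)
        mid = mf.exp_origin(T.mean(axis=0, keepdims=True), comp)
        np.testing.assert_allclose(out[0], mid[0], atol=1e-9)
        # the midpoint is equidistant from both inputs in tangent coordinates
        t_out = mf.log_origin(out, comp)
        d0 = np.linalg.norm(t_out[0] - T[0])
        d1 = np.linalg.norm(t_out[1] - T[1])
        assert abs(float(d0) - float(d1)) <= 1e-6

    def test_outputs_stay_on_manifold(self):
        comp = Component(mf.HYPERBOLIC, 5, 2.0)
        g = generate_synthetic("cycle", {"n": 8})
        A = normalized_adjacency(g)
        rng = np.random.default_rng(4)
        layer = GCNLayer(
            LayerSpec(5, 5, comp, use_bias=True), rng.standard_normal((5, 5)), rng.standard_normal(5)
        )
        P = mf.random_points(comp, 8, rng)
        out = tangent_gcn_layer(P, A, layer)
        assert mf.constraint_residual(out, comp).max() <= 1e-5


class TestDecoder:
    def test_coincident_points_score_above_half(self):
        model = ProductGCNModel.build(Signature.parse("S3_1 x E2"), seed=0)
        p = [mf.origin(c) for c in model.signature]
        s = decode_edge(p, p, model)
        assert all(cs > 0.5 for cs in s.component_scores)

    def test_far_points_score_near_zero(self):
        assert fermi_dirac(np.array([1e6]), 2.0, 1.0)[0] == pytest.approx(0.0, abs=1e-10)

    def test_final_score_is_component_mean(self):
        sig = Signature.parse("E2 x E2")
        model = ProductGCNModel.build(sig, seed=0)
        u = [np.zeros(2), np.zeros(2)]
        v = [np.array([1.0, 0.0]), np.array([3.0, 0.0])]
        s = decode_edge(u, v, model)
        assert s.score == pytest.approx(float(s.component_scores.mean()), abs=1e-12)

    def test_score_decreases_with_distance(self):
        dgrid = np.linspace(0.0, 5.0, 40)
        scores = fermi_dirac(dgrid**2, 2.0, 1.0)
        assert np.all(np.diff(scores) < 0)


class TestBackprop:
    def test_parameter_gradients_match_finite_differences(self):
        g = generate_synthetic("cycle", {"n": 6})
        sig = Signature.parse("H2_1 x S2_2 x E2")
        model = ProductGCNModel.build(sig, depth=2, seed=0)
        rng = np.random.default_rng(1)
        blocks = [mf.random_points(c, 6, rng) for c in sig]
        A = normalized_adjacency(g)
        pairs = np.array([[0, 1], [2, 4], [3, 5]])
        labels = np.array([1.0, 0.0, 1.0])
        _, pgrads, _, _ = _loss_and_grads(model, blocks, A, pairs, labels)
        for pi, p in enumerate(model.parameters()):
            flat = p.reshape(-1)
            num = np.zeros_like(flat)
            for k in range(flat.size):
                for sgn in (1.0, -1.0):
                    flat[k] += sgn * 1e-6
                    l, _, _, _ = _loss_and_grads(model, blocks, A, pairs, labels)
                    num[k] += sgn * l / 2e-6
                    flat[k] -= sgn * 1e-6
            np.testing.assert_allclose(pgrads[pi].reshape(-1), num, atol=1e-6)


def _split_fixture(seed=0):
    g = generate_synthetic("planted_partition", {"n": 24, "p_in": 0.5, "p_out": 0.05}, seed=seed)
    split = split_edges(g, 0.1, seed=seed)
    tg = PathwayGraph(g.nodes, frozenset(split.train_edges))
    return g, tg, split


class TestTraining:
    def test_zero_epochs_returns_initial_metrics(self):
        g, tg, split = _split_fixture()
        sig = Signature.parse("E8")
        model = ProductGCNModel.build(sig, seed=0)
        X = np.random.default_rng(2).standard_normal((g.n_nodes, 8))
        _, trace = riemannian_adam_fit(
            model, tg, [X], split.train_edges, split.val_edges, GCNHyperparams(epochs=0, seed=0)
        )
        assert len(trace.val_auroc) == 1 and not trace.loss

    def test_on_manifold_throughout_training(self):
        g, tg, split = _split_fixture(1)
        sig = Signature.parse("H4_1 x S4_2")
        model = ProductGCNModel.build(sig, seed=1)
        rng = np.random.default_rng(3)
        blocks = [mf.random_points(c, g.n_nodes, rng) for c in sig]
        hp = GCNHyperparams(epochs=30, seed=1)
        model, _ = riemannian_adam_fit(model, tg, blocks, split.train_edges, split.val_edges, hp)
        A = normalized_adjacency(tg)
        for stack, X in zip(model.stacks, blocks):
            P = X
            for layer in stack.layers:
                P = tangent_gcn_layer(P, A, layer)
                assert mf.constraint_residual(P, layer.spec.component).max() <= 1e-5

    def test_planted_cliques_rank_heldout_intra_edges_higher(self):
        """Held-out intra-clique edges outscore random non-edges on average."""
        k = 8
        edges = [(f"a{i}", f"a{j}") for i, j in itertools.combinations(range(k), 2)]
        edges += [(f"b{i}", f"b{j}") for i, j in itertools.combinations(range(k), 2)]
        edges.append(("a0", "b0"))
        wins = 0
        for seed in range(5):
            g = PathwayGraph.from_edges(edges)
            split = split_edges(g, 0.1, seed=seed)
            tg = PathwayGraph(g.nodes, frozenset(split.train_edges))
            sig = Signature.parse("E8")
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((g.n_nodes, 8))
            model = ProductGCNModel.build(sig, seed=seed)
            hp = GCNHyperparams(learning_rate=0.05, epochs=50, seed=seed)
            model, _ = riemannian_adam_fit(model, tg, [X], split.train_edges, split.val_edges, hp)
            held = sorted(split.val_edges)
            rand = sorted(
                sample_negatives(g, len(held), exclude=frozenset(g.edges), seed=seed + 100)
            )
            pos = predict_scores(model, tg, [X], held)
            neg = predict_scores(model, tg, [X], rand)
            wins += float(np.mean(pos)) > float(np.mean(neg))
        assert wins >= 3

    def test_all_euclidean_product_gcn_matches_plain_gcn(self):
        """With an all-euclidean signature the product model is exactly a
        standard GCN with a Fermi-Dirac distance decoder."""
        g, tg, split = _split_fixture(2)
        dim = 12
        X = np.random.default_rng(5).standard_normal((g.n_nodes, dim))
        model = ProductGCNModel.build(Signature.parse(f"E{dim}"), depth=2, seed=7)
        hp = GCNHyperparams(learning_rate=0.01, epochs=40, seed=7, early_stopping=False)
        model, trace = riemannian_adam_fit(model, tg, [X], split.train_edges, split.val_edges, hp)
        plain = build_plain_gcn(dim, depth=2, seed=7)
        plain, ptrace = fit_plain_gcn(
            plain, tg, X, split.train_edges, split.val_edges, lr=0.01, epochs=40, seed=7, eval_every=5
        )
        np.testing.assert_allclose(trace.loss, ptrace["loss"], atol=1e-5)
        np.testing.assert_allclose(trace.val_auroc, ptrace["val_auroc"], atol=1e-5)
        np.testing.assert_allclose(model.stacks[0].layers[0].W, plain.weights[0], atol=1e-5)
        assert float(model.stacks[0].r) == pytest.approx(plain.r, abs=1e-5)

    def test_nan_gradient_aborts(self):
        opt = Adam([np.zeros(3)], lr=0.1)
        with pytest.raises(FloatingPointError):
            opt.step([np.array([np.nan, 0.0, 0.0])])
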