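import numpy as np
import pytest

from slidefactors.graph import WSIGraph, build_graph
from slidefactors.model import (
    ModelConfig,
    SlideGraphModel,
    ranking_loss,
    ranking_loss_grad,
)


def random_graph(rng, n=12, dim=6, dmax=2500.0):
    coords = rng.uniform(0, 5000, size=(n, 2))
    feats = rng.normal(size=(n, dim))
    return build_graph(coords, feats, edge_distance_max=dmax)


def small_model(dim=6, L=3, K=4, seed=0):
    return SlideGraphModel(
        ModelConfig(n_layers=L, n_outputs=K, layer_width=5,
                    layer_hidden_width=5, head_hidden_width=5, seed=seed),
        dim,
    )


class TestEdgeConvForward:
    def test_isolated_node_embeddings_are_exactly_zero(self):
        # two nodes too far apart to connect: empty neighborhoods
        g = build_graph(np.array([[0.0, 0.0], [9000.0, 0.0]]), np.ones((2, 6)))
        model = small_model()
        embeddings = model.edgeconv_forward(g)
        for h in embeddings[1:]:
            np.testing.assert_array_equal(h, np.zeros_like(h))

    def test_two_node_path_matches_manual_computation(self):
        g = build_graph(np.array([[0.0, 0.0], [100.0, 0.0]]),
                        np.array([[1.0, 2.0], [3.0, 5.0]]))
        model = SlideGraphModel(
            ModelConfig(n_layers=1, n_outputs=1, layer_width=2,
                        layer_hidden_width=2, head_hidden_width=2, seed=0), 2)
        conv = model.edgeconvs[0]
        h = g.features
        # by hand: h_m^1 = H([h_m || h_k - h_m]) for the single neighbor
        for m, k in ((0, 1), (1, 0)):
            x = np.concatenate([h[m], h[k] - h[m]])[None, :]
            z1 = x @ conv.W1 + conv.b1
            manual = np.maximum(z1, 0) @ conv.W2 + conv.b2
            np.testing.assert_allclose(
                model.edgeconv_forward(g)[1][m], manual[0], atol=1e-12)

    def test_feature_dim_mismatch_rejected(self, rng):
        g = random_graph(rng, dim=4)
        with pytest.raises(ValueError, match="dim"):
            small_model(dim=6).edgeconv_forward(g)


class TestLocality:
    def test_node_score_invariant_beyond_L_hops(self, rng):
        # chain graph: node 0's receptive field is exactly L hops
        n, L = 8, 3
        coords = np.stack([np.arange(n) * 1000.0, np.zeros(n)], axis=1)
        feats = rng.normal(size=(n, 6))
        g = build_graph(coords, feats, edge_distance_max=1000.0)
        model = small_model(L=L)
        head_rng = np.random.default_rng(5)
        for head in model.heads:  # non-zero outputs so scores see embeddings
            head.W2[...] = head_rng.normal(size=head.W2.shape)
        base = model.node_scores(g)[0]
        far = feats.copy()
        far[L + 1 :] += rng.normal(size=(n - L - 1, 6)) * 10  # beyond L hops
        g2 = WSIGraph(g.slide_id, g.coords, far, g.edges)
        np.testing.assert_array_equal(model.node_scores(g2)[0], base)
        near = feats.copy()
        near[L] += 1.0  # exactly L hops away: inside the receptive field
        g3 = WSIGraph(g.slide_id, g.coords, near, g.edges)
        assert not np.array_equal(model.node_scores(g3)[0], base)


class TestScores:
    def test_zero_head_parameters_give_zero_scores(self, rng):
        g = random_graph(rng)
        model = small_model()
        for head in model.heads:
            head.set_params([np.zeros_like(p) for p in head.params])
        np.testing.assert_array_equal(model.node_scores(g), 0.0)

    def test_L0_score_is_layer0_head_only(self, rng):
        g = random_graph(rng)
        model = small_model(L=0)
        out, _ = model.heads[0].forward(g.features)
        np.testing.assert_allclose(model.node_scores(g), out)

    def test_node_score_is_sum_of_head_outputs(self, rng):
        g = random_graph(rng, n=5)
        model = small_model()
        embeddings = model.edgeconv_forward(g)
        oracle = sum(h.forward(e)[0] for h, e in zip(model.heads, embeddings))
        np.testing.assert_allclose(model.node_scores(g), oracle, atol=1e-12)

    def test_slide_score_is_node_score_sum(self, rng):
        g = random_graph(rng, n=30)
        model = small_model()
        np.testing.assert_allclose(
            model.slide_score(g), model.node_scores(g).sum(axis=0), rtol=1e-5)

    def test_single_node_slide_score(self, rng):
        g = build_graph(np.array([[0.0, 0.0]]), rng.normal(size=(1, 6)))
        model = small_model()
        np.testing.assert_allclose(model.slide_score(g),
                                   model.node_scores(g)[0])

    def test_disconnected_components_additive(self, rng):
        # two clusters farther apart than the prune distance
        a = rng.uniform(0, 1000, size=(6, 2))
        b = rng.uniform(20000, 21000, size=(5, 2))
        fa, fb = rng.normal(size=(6, 6)), rng.normal(size=(5, 6))
        model = small_model()
        joint = build_graph(np.vstack([a, b]), np.vstack([fa, fb]),
                            edge_distance_max=2500.0)
        ga = build_graph(a, fa, edge_distance_max=2500.0)
        gb = build_graph(b, fb, edge_distance_max=2500.0)
        np.testing.assert_allclose(
            model.slide_score(joint),
            model.slide_score(ga) + model.slide_score(gb), atol=1e-9)

    def test_permutation_equivariance(self, rng):
        g = random_graph(rng, n=15)
        model = small_model()
        perm = rng.permutation(g.n_nodes)
        inv = np.argsort(perm)
        g2 = build_graph(g.coords[perm], g.features[perm])
        np.testing.assert_allclose(model.node_scores(g2)[inv],
                                   model.node_scores(g), atol=1e-9)
        np.testing.assert_allclose(model.slide_score(g2),
                                   model.slide_score(g), atol=1e-9)


class TestRankingLoss:
    def test_separated_pair_has_zero_loss(self):
        assert ranking_loss(np.array([[2.0], [0.0]]), np.array([[1.0], [0.0]])) == 0

    def test_equal_scores_closed_form(self):
        # p positives, q negatives, all scores equal -> loss = p*q
        scores = np.zeros((7, 1))
        labels = np.array([1, 1, 1, 0, 0, 0, 0], dtype=float)[:, None]
        assert ranking_loss(scores, labels) == 3 * 4

    def test_half_margin(self):
        loss = ranking_loss(np.array([[0.5], [0.0]]), np.array([[1.0], [0.0]]))
        assert loss == pytest.approx(0.5)

    def test_missing_labels_excluded(self):
        scores = np.array([[5.0], [0.0], [0.0]])
        labels = np.array([[1.0], [np.nan], [0.0]])
        assert ranking_loss(scores, labels) == 0.0

    def test_single_class_output_contributes_zero(self):
        scores = np.random.default_rng(0).normal(size=(4, 2))
        labels = np.column_stack([np.ones(4), np.array([1, 1, 0, 0])])
        only_k2 = ranking_loss(scores, labels)
        assert only_k2 == ranking_loss(scores[:, 1:], labels[:, 1:])

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_bruteforce_double_loop(self, trial):
        rng = np.random.default_rng(trial)
        n, k = int(rng.integers(2, 9)), int(rng.integers(1, 6))
        scores = rng.normal(size=(n, k))
        labels = rng.choice([0.0, 1.0, np.nan], size=(n, k), p=[0.4, 0.4, 0.2])
        expected = 0.0
        for kk in range(k):
            for a in range(n):
                for b in range(n):
                    if labels[a, kk] == 1 and labels[b, kk] == 0:
                        expected += max(0.0, 1 - (scores[a, kk] - scores[b, kk]))
        assert ranking_loss(scores, labels) == pytest.approx(expected)


class TestGradients:
    @pytest.mark.parametrize("L", [0, 1, 3])
    def test_backprop_matches_numerical_gradient(self, L, rng):
        g = random_graph(rng, n=7, dim=5)
        model = small_model(dim=5, L=L, K=3, seed=1)
        # randomise head outputs so score gradients are non-trivial
        head_rng = np.random.default_rng(2)
        for head in model.heads:
            p = head.params
            p[2][...] = head_rng.normal(size=p[2].shape)
        gs = np.array([1.0, -0.5, 2.0])
        _, grads = model.slide_grad(g, gs)
        eps = 1e-6
        for pi, p in enumerate(model.params):
            flat = p.ravel()
            idx = rng.choice(flat.size, size=min(6, flat.size), replace=False)
            for j in idx:
                old = flat[j]
                flat[j] = old + eps
                s1 = gs @ model.slide_score(g)
                flat[j] = old - eps
                s2 = gs @ model.slide_score(g)
                flat[j] = old
                assert (s1 - s2) / (2 * eps) == pytest.approx(
                    grads[pi].ravel()[j], abs=1e-5)

    def test_ranking_loss_grad_matches_numerical(self, rng):
        scores = rng.normal(size=(6, 3))
        labels = rng.choice([0.0, 1.0], size=(6, 3))
        _, grad = ranking_loss_grad(scores, labels)
        eps = 1e-6
        for i in range(6):
            for j in range(3):
                s1 = scores.copy(); s1[i, j] += eps
                s2 = scores.copy(); s2[i, j] -= eps
                num = (ranking_loss(s1, labels) - ranking_loss(s2, labels)) / (2 * eps)
                assert num == pytest.approx(grad[i, j], abs=1e-4)

    def test_clone_and_params_round_trip(self, rng):
        g = random_graph(rng)
        model = small_model()
        other = model.clone()
        np.testing.assert_array_equal(model.node_scores(g),
                                      other.node_scores(g))
        other.params[0][...] += 1.0  # mutating the clone's refs...
        # ...must not touch the original (clone copies parameters)
        assert not np.array_equal(other.params[0], model.params[0])
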