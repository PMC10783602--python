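"""Multi-output EdgeConv graph network with per-layer node heads.

Message passing follows the EdgeConv update with SUM aggregation over the
neighborhood N(m):

    h_m^l = sum_{k in N(m)} H^l( [ h_m^{l-1} || h_k^{l-1} - h_m^{l-1} ] )

where H^l is a small perceptron.  A head f_l maps each layer's embedding
(including layer 0, the raw patch features) to K scores; the node score is
f(v_m) = sum_{l=0..L} f_l(h_m^l) and the slide score is the sum of node
scores, F(G) = sum_m f(v_m).  Training uses a pairwise hinge ranking loss per
output: within a batch, every status-1 slide must outscore every status-0
slide by margin 1.

Isolated nodes have empty neighborhoods, so their embeddings are exactly zero
at every layer l >= 1, and a node's score depends only on nodes within L hops
(the receptive field of L EdgeConv layers).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph import WSIGraph
from .nn import MLP

RANKING_MARGIN = 1.0


@dataclass
class ModelConfig:
    n_layers: int = 3            # L EdgeConv layers
    n_outputs: int = 200         # K gene groups scored simultaneously
    layer_width: int = 16        # embedding dim of each EdgeConv output
    layer_hidden_width: int = 16  # hidden width of the message networks H^l
    head_hidden_width: int = 64   # hidden width of the heads f_l
    activation: str = "relu"          # message networks H^l
    head_activation: str = "identity"  # heads f_l (linear scoring path)
    # fixed multiplier on head outputs: slide scores sum hundreds of node
    # scores, so a small output scale keeps ranking margins unsaturated for
    # many more optimizer steps, averaging the gradient over more slide pairs
    # before the hinge goes silent
    score_scale: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_layers < 0 or self.n_outputs < 1:
            raise ValueError("need n_layers >= 0 and n_outputs >= 1")


@dataclass
class Prediction:
    """Per-node and per-slide scores for one slide."""

    slide_id: str
    node_scores: np.ndarray   # (n_nodes, K)
    slide_scores: np.ndarray  # (K,) = column sum of node_scores


class SlideGraphModel:
    """EdgeConv stack H^1..H^L plus heads f_0..f_L (L+1 heads)."""

    def __init__(self, config: ModelConfig, feature_dim: int):
        self.config = config
        self.feature_dim = feature_dim
        rng = np.random.default_rng(config.seed)
        dims = [feature_dim] + [config.layer_width] * config.n_layers
        # message nets: output init scaled down by the typical Delaunay degree
        # (~6) so sum aggregation keeps embeddings near unit scale at init
        self.edgeconvs = [
            MLP(2 * dims[l], config.layer_hidden_width, dims[l + 1], rng,
                output_scale=1.0 / 6.0, activation=config.activation)
            for l in range(config.n_layers)
        ]
        self.heads = [
            MLP(dims[l], config.head_hidden_width, config.n_outputs, rng,
                zero_output=True, activation=config.head_activation)
            for l in range(config.n_layers + 1)
        ]
        # smoothing start: with the difference-block of W1 equal to the node
        # block, H^l([h_m || h_k - h_m]) = A h_k at init, so each layer begins
        # as a random projection of the neighborhood sum (a spatial smoother
        # with sqrt(degree) noise averaging); training departs from it freely
        for conv in self.edgeconvs:
            d_in = conv.W1.shape[0] // 2
            conv.W1[d_in:] = conv.W1[:d_in]

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for net in [*self.edgeconvs, *self.heads]:
            out.extend(net.params)
        return out

    def set_params(self, params: list[np.ndarray]) -> None:
        it = iter(params)
        for net in [*self.edgeconvs, *self.heads]:
            net.set_params([next(it) for _ in range(4)])

    def clone(self) -> "SlideGraphModel":
        other = SlideGraphModel(self.config, self.feature_dim)
        other.set_params(self.params)
        return other

    # -- forward ------------------------------------------------------------
    def _check(self, graph: WSIGraph) -> None:
        if graph.feature_dim != self.feature_dim:
            raise ValueError(
                f"graph feature dim {graph.feature_dim} != model input dim "
                f"{self.feature_dim}"
            )

    @staticmethod
    def _scatter(graph: WSIGraph):
        """Directed edge endpoints plus cached sparse scatter operators."""
        if graph._adj is None:
            from scipy.sparse import csr_matrix

            de = graph.directed_edges()
            n, e = graph.n_nodes, len(de)
            m = de[:, 0] if e else np.empty(0, int)
            k = de[:, 1] if e else np.empty(0, int)
            ones = np.ones(e)
            sm = csr_matrix((ones, (m, np.arange(e))), shape=(n, e))
            sk = csr_matrix((ones, (k, np.arange(e))), shape=(n, e))
            graph._adj = (m, k, sm, sk)
        return graph._adj

    def edgeconv_forward(self, graph: WSIGraph, with_cache: bool = False):
        """Embeddings h^0..h^L per node (h^0 = input features)."""
        self._check(graph)
        m, k, sm, _ = self._scatter(graph)
        h = graph.features
        embeddings = [h]
        caches = []
        for conv in self.edgeconvs:
            x = np.concatenate([h[m], h[k] - h[m]], axis=1)
            msg, cache = conv.forward(x)
            h_new = sm @ msg  # sum over each node's outgoing directed edges
            caches.append(cache)
            embeddings.append(h_new)
            h = h_new
        return (embeddings, caches, (m, k)) if with_cache else embeddings

    def node_scores(self, graph: WSIGraph) -> np.ndarray:
        embeddings = self.edgeconv_forward(graph)
        scores = np.zeros((graph.n_nodes, self.config.n_outputs))
        for head, h in zip(self.heads, embeddings):
            out, _ = head.forward(h)
            scores += out
        return self.config.score_scale * scores

    def slide_score(self, graph: WSIGraph) -> np.ndarray:
        if graph.n_nodes == 0:
            raise ValueError("empty graph has no slide score")
        return self.node_scores(graph).sum(axis=0)

    def predict(self, graph: WSIGraph) -> Prediction:
        ns = self.node_scores(graph)
        return Prediction(graph.slide_id, ns, ns.sum(axis=0))

    # -- backward -----------------------------------------------------------
    def forward_pass(self, graph: WSIGraph):
        """Slide score plus the cached state needed by :meth:`backward_pass`."""
        embeddings, conv_caches, (m, k) = self.edgeconv_forward(graph, with_cache=True)
        n = graph.n_nodes
        head_caches = []
        scores = np.zeros((n, self.config.n_outputs))
        for head, h in zip(self.heads, embeddings):
            out, cache = head.forward(h)
            head_caches.append(cache)
            scores += out
        scores *= self.config.score_scale
        state = (embeddings, conv_caches, head_caches, graph)
        return scores.sum(axis=0), state

    def backward_pass(self, state, g_slide: np.ndarray) -> list[np.ndarray]:
        """Parameter gradients given dL/d(slide score) (K,).  Because the
        slide score is the node-score sum, every node's score shares the same
        upstream gradient."""
        embeddings, conv_caches, head_caches, graph = state
        m, k, sm, sk = self._scatter(graph)
        n = embeddings[0].shape[0]
        g_nodes = np.broadcast_to(self.config.score_scale * g_slide,
                                  (n, len(g_slide)))
        g_h = [np.zeros_like(h) for h in embeddings]
        grads_heads = []
        for head, cache, l in zip(self.heads, head_caches, range(len(self.heads))):
            gh, g = head.backward(cache, g_nodes)
            g_h[l] += gh
            grads_heads.append(g)
        grads_convs = [None] * len(self.edgeconvs)
        for l in range(len(self.edgeconvs) - 1, -1, -1):
            conv = self.edgeconvs[l]
            g_msg = g_h[l + 1][m]
            gx, grads_convs[l] = conv.backward(conv_caches[l], g_msg)
            d = embeddings[l].shape[1]
            ga, gb = gx[:, :d], gx[:, d:]
            g_h[l] += sm @ (ga - gb) + sk @ gb

        flat = []
        for g in [*grads_convs, *grads_heads]:
            flat.extend(g)
        return flat

    def slide_grad(self, graph: WSIGraph, g_slide: np.ndarray):
        """Convenience: one forward + backward; returns (slide score, grads)."""
        score, state = self.forward_pass(graph)
        return score, self.backward_pass(state, g_slide)


def ranking_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Pairwise hinge: sum_k sum_{(a,b): y_a=1, y_b=0} max(0, 1 - (s_a - s_b)).

    ``labels`` may contain NaN for missing entries; a slide missing its label
    for output k simply contributes no pairs for that k.
    """
    loss, _ = ranking_loss_grad(scores, labels)
    return loss


def ranking_loss_grad(scores: np.ndarray, labels: np.ndarray):
    """Loss and its gradient with respect to the score matrix."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if labels.ndim == 1:
        labels = labels[:, None]
    loss = 0.0
    grad = np.zeros_like(scores)
    for col in range(scores.shape[1]):
        y = labels[:, col]
        s = scores[:, col]
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        if len(pos) == 0 or len(neg) == 0:
            continue
        margin = RANKING_MARGIN - (s[pos][:, None] - s[neg][None, :])
        active = margin > 0
        loss += float(margin[active].sum())
        grad[pos, col] -= active.sum(axis=1)
        grad[neg, col] += active.sum(axis=0)
    return loss, grad
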