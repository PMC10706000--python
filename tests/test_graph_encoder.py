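"""Graph-attention layer against an explicit per-neighborhood oracle."""

import numpy as np
import pytest

from graphgpt import mol_to_graph
from graphgpt.chem import MolecularGraph
from graphgpt.graph_encoder import GATHead, GATLayer, GraphEncoder, GraphEncoderConfig
from graphgpt.nn import Tensor


def brute_force_attention(h, W, a_src, a_dst, adj, slope=0.2):
    """Direct evaluation: e_ij = LeakyReLU(a^T [Wh_i || Wh_j]), softmax over
    each explicit neighborhood (self included)."""
    n = h.shape[0]
    wh = h @ W
    coeff = np.zeros((n, n))
    for i in range(n):
        neigh = [j for j in range(n) if adj[i, j] > 0]
        scores = []
        for j in neigh:
            e = a_src @ wh[i] + a_dst @ wh[j]
            scores.append(e if e > 0 else slope * e)
        scores = np.asarray(scores)
        weights = np.exp(scores - scores.max())
        weights /= weights.sum()
        for j, w in zip(neigh, weights):
            coeff[i, j] = w
    return coeff, wh


def random_graph(rng, n_nodes, n_features=8, p_edge=0.4):
    edges = [
        (i, j)
        for i in range(n_nodes)
        for j in range(i + 1, n_nodes)
        if rng.random() < p_edge
    ]
    feats = np.zeros((n_nodes, n_features))
    feats[np.arange(n_nodes), rng.integers(0, n_features, n_nodes)] = 1.0
    return MolecularGraph(node_features=feats, edges=edges, num_nodes=n_nodes)


class TestGATHead:
    def test_single_node_attends_to_itself(self, rng):
        head = GATHead(4, 3, rng, 0.2)
        coeff, _ = head.attention(Tensor(rng.normal(size=(1, 4))), np.ones((1, 1)))
        assert coeff.data[0, 0] == pytest.approx(1.0)

    def test_identical_features_split_evenly(self, rng):
        head = GATHead(4, 3, rng, 0.2)
        h = np.tile(rng.normal(size=4), (2, 1))
        coeff, _ = head.attention(Tensor(h), np.ones((2, 2)))
        np.testing.assert_allclose(coeff.data, np.full((2, 2), 0.5), atol=1e-12)

    def test_three_node_path_matches_hand_evaluation(self, rng):
        head = GATHead(2, 2, rng, 0.2)
        h = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        adj = np.array([[1, 1, 0], [1, 1, 1], [0, 1, 1]], dtype=float)
        coeff, _ = head.attention(Tensor(h), adj)
        expected, _ = brute_force_attention(
            h, head.W.data, head.a_src.data, head.a_dst.data, adj
        )
        np.testing.assert_allclose(coeff.data, expected, atol=1e-6)

    def test_dense_equivalence_on_small_random_graphs(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 7))
            graph = random_graph(rng, n)
            head = GATHead(8, 4, rng, 0.2)
            adj = graph.adjacency()
            coeff, wh = head.attention(Tensor(graph.node_features), adj)
            expected, wh_expected = brute_force_attention(
                graph.node_features, head.W.data, head.a_src.data, head.a_dst.data, adj
            )
            np.testing.assert_allclose(coeff.data, expected, atol=1e-6)
            # full head output: sigmoid of coefficient-weighted aggregation
            out = head(Tensor(graph.node_features), adj)
            np.testing.assert_allclose(
                out.data, 1 / (1 + np.exp(-(expected @ wh_expected))), atol=1e-6
            )


class TestRowStochasticity:
    def test_all_layers_all_heads_on_fixture_graphs(self, rng, fixture_smiles):
        config = GraphEncoderConfig(hidden_dim=4, out_dim=8, heads=4)
        encoder = GraphEncoder(config, rng).eval()
        for smi in fixture_smiles[:20]:
            graph = mol_to_graph(smi)
            adj = graph.adjacency()
            h = Tensor(graph.node_features)
            for layer in (encoder.layer1, encoder.layer2):
                for coeff in layer.attention_coefficients(h, adj):
                    np.testing.assert_allclose(coeff.sum(axis=1), 1.0, atol=1e-6)
                    assert (coeff >= 0).all()
                    assert (coeff[adj == 0] == 0).all()
                h = layer(h, adj)


class TestEncodeGraph:
    def test_permutation_invariance(self, rng):
        config = GraphEncoderConfig(in_dim=8, hidden_dim=4, out_dim=8, heads=2)
        encoder = GraphEncoder(config, rng).eval()
        for _ in range(100):
            n = int(rng.integers(2, 9))
            graph = random_graph(rng, n)
            perm = rng.permutation(n)
            inv = np.argsort(perm)
            permuted = MolecularGraph(
                node_features=graph.node_features[perm],
                edges=[(int(inv[i]), int(inv[j])) for i, j in graph.edges],
                num_nodes=n,
            )
            np.testing.assert_allclose(
                encoder.encode_graph(graph), encoder.encode_graph(permuted), atol=1e-10
            )

    def test_single_node_embedding_is_its_feature_row(self, rng):
        config = GraphEncoderConfig(in_dim=6, hidden_dim=4, out_dim=5, heads=2)
        encoder = GraphEncoder(config, rng).eval()
        graph = random_graph(rng, 1, n_features=6)
        h = encoder.layer1(Tensor(graph.node_features), graph.adjacency())
        h = encoder.layer2(h, graph.adjacency())
        expected = np.maximum(h.data[0], 0.0)
        np.testing.assert_allclose(encoder.encode_graph(graph), expected, atol=1e-12)

    def test_deterministic_in_eval_mode(self, rng):
        config = GraphEncoderConfig(in_dim=8, hidden_dim=4, out_dim=8)
        encoder = GraphEncoder(config, rng).eval()
        graph = random_graph(rng, 5)
        a = encoder.encode_graph(graph)
        b = encoder.encode_graph(graph)
        np.testing.assert_array_equal(a, b)
        assert (a >= 0).all()  # post-ReLU max pool
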