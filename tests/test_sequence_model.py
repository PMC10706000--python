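"""Causal decoder: attention oracle, causality probes, pooling mapper."""

import numpy as np
import pytest

from graphgpt.nn import Tensor
from graphgpt.sequence_model import MiniGPT, MiniGPTConfig, causal_attention


def brute_force_causal_attention(q, k, v):
    """Row-by-row masked softmax(QK^T / sqrt(d_k)) V."""
    t, dk = q.shape
    out = np.zeros_like(v)
    for i in range(t):
        scores = np.array([q[i] @ k[j] / np.sqrt(dk) for j in range(i + 1)])
        w = np.exp(scores - scores.max())
        w /= w.sum()
        out[i] = sum(w[j] * v[j] for j in range(i + 1))
    return out


@pytest.fixture()
def tiny_model(rng):
    config = MiniGPTConfig(
        vocab_size=12, n_layers=2, n_heads=2, d_model=16, max_len=20,
        dropout=0.0, alignment_dim=8, n_properties=1,
    )
    return MiniGPT(config, rng).eval()


class TestCausalAttention:
    def test_identical_keys_attend_uniformly(self, rng):
        t, d = 5, 4
        k = np.tile(rng.normal(size=d), (t, 1))
        q = rng.normal(size=(t, d))
        v = rng.normal(size=(t, d))
        _, weights = causal_attention(Tensor(q), Tensor(k), Tensor(v))
        for i in range(t):
            np.testing.assert_allclose(weights.data[i, : i + 1], 1.0 / (i + 1), atol=1e-12)

    def test_pinned_matrices_match_brute_force(self, rng):
        q = rng.normal(size=(3, 2))
        k = rng.normal(size=(3, 2))
        v = rng.normal(size=(3, 2))
        out, _ = causal_attention(Tensor(q), Tensor(k), Tensor(v))
        np.testing.assert_allclose(out.data, brute_force_causal_attention(q, k, v), atol=1e-6)

    def test_multi_head_batch_matches_per_head_brute_force(self, rng):
        b, h, t, dk = 2, 3, 5, 4
        q, k, v = (rng.normal(size=(b, h, t, dk)) for _ in range(3))
        out, _ = causal_attention(Tensor(q), Tensor(k), Tensor(v))
        for bi in range(b):
            for hi in range(h):
                np.testing.assert_allclose(
                    out.data[bi, hi],
                    brute_force_causal_attention(q[bi, hi], k[bi, hi], v[bi, hi]),
                    atol=1e-6,
                )

    def test_future_weights_exactly_zero(self, rng):
        q, k, v = (rng.normal(size=(1, 2, 6, 3)) for _ in range(3))
        _, weights = causal_attention(Tensor(q), Tensor(k), Tensor(v))
        assert (np.triu(weights.data[0, 0], k=1) == 0).all()
        np.testing.assert_allclose(weights.data.sum(axis=-1), 1.0, atol=1e-6)


class TestForward:
    def test_output_shape(self, tiny_model, rng):
        ids = rng.integers(0, 12, size=(2, 10))
        logits, hidden, _ = tiny_model.forward(ids)
        assert logits.shape == (2, 10, 12)
        assert hidden.shape == (2, 10, 16)

    def test_eval_mode_deterministic(self, tiny_model, rng):
        ids = rng.integers(0, 12, size=(1, 8))
        a, _, _ = tiny_model.forward(ids)
        b, _, _ = tiny_model.forward(ids)
        np.testing.assert_array_equal(a.data, b.data)

    def test_no_causal_leakage_under_perturbation(self, tiny_model, rng):
        for _ in range(20):
            ids = rng.integers(0, 12, size=(1, 12))
            t = int(rng.integers(0, 11))
            perturbed = ids.copy()
            pos = int(rng.integers(t + 1, 12))
            perturbed[0, pos] = (perturbed[0, pos] + 1) % 12
            base, _, _ = tiny_model.forward(ids)
            after, _, _ = tiny_model.forward(perturbed)
            np.testing.assert_array_equal(base.data[:, : t + 1], after.data[:, : t + 1])

    def test_attention_rows_sum_to_one_everywhere(self, tiny_model, rng):
        ids = rng.integers(0, 12, size=(2, 9))
        _, _, maps = tiny_model.forward(ids, collect_attention=True)
        assert len(maps) == 2  # layers
        for m in maps:
            assert m.shape == (2, 2, 9, 9)
            np.testing.assert_allclose(m.sum(axis=-1), 1.0, atol=1e-6)

    def test_out_of_vocab_id_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.array([[99]]))

    def test_property_slot_injection_changes_embedding(self, tiny_model):
        ids = np.array([[3, 1, 4, 2]])
        onehot = np.zeros((1, 4, 1))
        onehot[0, 0, 0] = 1.0
        lo = tiny_model.forward(ids, prop_onehot=onehot, prop_values=np.array([[0.0]*4]))[0]
        hi = tiny_model.forward(ids, prop_onehot=onehot, prop_values=np.array([[2.0, 0, 0, 0]]))[0]
        assert not np.allclose(lo.data, hi.data)


class TestMapper:
    def test_identical_sequences_identical_embeddings(self, tiny_model, rng):
        ids = rng.integers(0, 12, size=(2, 6))
        ids[1] = ids[0]
        _, hidden, _ = tiny_model.forward(ids)
        emb = tiny_model.map_sequence_embedding(hidden, np.ones((2, 6), dtype=bool))
        np.testing.assert_allclose(emb.data[0], emb.data[1], atol=1e-12)

    def test_padding_does_not_change_embedding(self, tiny_model, rng):
        ids = rng.integers(1, 12, size=(1, 5))
        padded = np.concatenate([ids, np.zeros((1, 3), dtype=int)], axis=1)
        _, hidden_short, _ = tiny_model.forward(ids)
        _, hidden_padded, _ = tiny_model.forward(padded)
        mask_short = np.ones((1, 5), dtype=bool)
        mask_padded = np.concatenate([mask_short, np.zeros((1, 3), dtype=bool)], axis=1)
        a = tiny_model.map_sequence_embedding(hidden_short, mask_short)
        b = tiny_model.map_sequence_embedding(hidden_padded, mask_padded)
        np.testing.assert_allclose(a.data, b.data, atol=1e-10)
        assert a.shape == (1, 8)  # alignment dim d

    def test_fully_masked_raises(self, tiny_model, rng):
        ids = rng.integers(0, 12, size=(1, 4))
        _, hidden, _ = tiny_model.forward(ids)
        with pytest.raises(ValueError):
            tiny_model.map_sequence_embedding(hidden, np.zeros((1, 4), dtype=bool))
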