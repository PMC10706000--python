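"""GPT-style causal decoder over condition-prefixed SMILES sequences.

Defaults follow the compact configuration the model family uses: 8 decoder
blocks, 8 attention heads, d_model = 256, maximum sequence length 100.
Blocks are pre-layer-norm: LN -> masked multi-head attention -> residual ->
LN -> 4x feed-forward (GELU) -> residual.  Position embeddings are learned
absolute embeddings.

Conditioned property values enter at the embedding layer: each conditioned
property owns a reserved prefix slot whose embedding is an affine map
``value * w_p + b_p`` of the scalar target, replacing the marker token's
embedding.  A fully connected mapper pools the final hidden states over
non-PAD positions and projects them into the graph-alignment space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Dropout, Embedding, LayerNorm, Linear, Module, Tensor, softmax

_NEG_INF = -1e9


@dataclass
class MiniGPTConfig:
    vocab_size: int
    n_layers: int = 8
    n_heads: int = 8
    d_model: int = 256
    max_len: int = 100
    dropout: float = 0.1
    alignment_dim: int = 64  # dim d of the graph-alignment space
    n_properties: int = 0  # conditioned property slots in the schema

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


def causal_attention(q: Tensor, k: Tensor, v: Tensor) -> tuple[Tensor, Tensor]:
    """Scaled dot-product attention with a strict causal mask.

    ``q, k, v`` share trailing shape (..., T, d_k); position t attends only to
    positions <= t.  Returns (output, attention weights); each weight row sums
    to 1 over the visible positions and future positions carry exactly 0.
    """
    q = q if isinstance(q, Tensor) else Tensor(q)
    k = k if isinstance(k, Tensor) else Tensor(k)
    v = v if isinstance(v, Tensor) else Tensor(v)
    d_k = q.shape[-1]
    scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    t = scores.shape[-1]
    future = np.triu(np.ones((t, t), dtype=bool), k=1)
    scores = scores + Tensor(np.where(future, _NEG_INF, 0.0))
    weights = softmax(scores, axis=-1)
    # exact zeros on future positions (softmax leaves ~e^-1e9 ~ 0 already)
    weights = weights * Tensor(np.where(future, 0.0, 1.0))
    return weights @ v, weights


class CausalSelfAttention(Module):
    def __init__(self, config: MiniGPTConfig, rng: np.random.Generator):
        super().__init__()
        d = config.d_model
        self.n_heads = config.n_heads
        self.qkv = Linear(d, 3 * d, rng)
        self.proj = Linear(d, d, rng)
        self.drop = Dropout(config.dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None):
        b, t, d = x.shape
        h = self.n_heads
        dk = d // h
        qkv = self.qkv(x)  # (B, T, 3d)
        q = qkv[:, :, :d].reshape(b, t, h, dk).transpose(0, 2, 1, 3)
        k = qkv[:, :, d : 2 * d].reshape(b, t, h, dk).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * d :].reshape(b, t, h, dk).transpose(0, 2, 1, 3)
        out, weights = causal_attention(q, k, v)  # (B, H, T, dk), (B, H, T, T)
        out = out.transpose(0, 2, 1, 3).reshape(b, t, d)
        return self.drop(self.proj(out), rng), weights


class Block(Module):
    def __init__(self, config: MiniGPTConfig, rng: np.random.Generator):
        super().__init__()
        d = config.d_model
        self.ln1 = LayerNorm(d)
        self.attn = CausalSelfAttention(config, rng)
        self.ln2 = LayerNorm(d)
        self.fc1 = Linear(d, 4 * d, rng)
        self.fc2 = Linear(4 * d, d, rng)
        self.drop = Dropout(config.dropout)

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None):
        attn_out, weights = self.attn(self.ln1(x), rng)
        x = x + attn_out
        x = x + self.drop(self.fc2(self.fc1(self.ln2(x)).gelu()), rng)
        return x, weights


class MiniGPT(Module):
    def __init__(self, config: MiniGPTConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        d = config.d_model
        self.token_emb = Embedding(config.vocab_size, d, rng)
        self.pos_emb = Tensor(rng.normal(0.0, 0.02, size=(config.max_len, d)), requires_grad=True)
        self.drop = Dropout(config.dropout)
        self.blocks = [Block(config, rng) for _ in range(config.n_layers)]
        self.ln_f = LayerNorm(d)
        self.head = Linear(d, config.vocab_size, rng, bias=False)
        self.mapper = Linear(d, config.alignment_dim, rng)
        if config.n_properties:
            # affine injection of scalar targets: value * W_p[p] + B_p[p]
            self.prop_w = Tensor(rng.normal(0.0, 0.02, size=(config.n_properties, d)), requires_grad=True)
            self.prop_b = Tensor(rng.normal(0.0, 0.02, size=(config.n_properties, d)), requires_grad=True)
        else:
            self.prop_w = None
            self.prop_b = None

    # ------------------------------------------------------------------ core
    def embed(
        self,
        ids: np.ndarray,
        prop_onehot: np.ndarray | None = None,
        prop_values: np.ndarray | None = None,
    ) -> Tensor:
        ids = np.asarray(ids)
        if ids.max(initial=0) >= self.config.vocab_size or ids.min(initial=0) < 0:
            raise ValueError("token id outside the vocabulary")
        b, t = ids.shape
        if t > self.config.max_len:
            raise ValueError(f"sequence length {t} exceeds max_len {self.config.max_len}")
        x = self.token_emb(ids) + self.pos_emb[:t]
        if prop_onehot is not None and self.prop_w is not None:
            onehot = Tensor(prop_onehot)  # (B, T, P), constant
            slot_mask = prop_onehot.sum(axis=-1, keepdims=True)  # (B, T, 1)
            injected = (onehot @ self.prop_w) * Tensor(
                np.asarray(prop_values)[..., None]
            ) + onehot @ self.prop_b
            x = x * Tensor(1.0 - slot_mask) + injected
        return x

    def forward(
        self,
        ids: np.ndarray,
        prop_onehot: np.ndarray | None = None,
        prop_values: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
        collect_attention: bool = False,
    ) -> tuple[Tensor, Tensor, list[np.ndarray]]:
        """Run the decoder; returns (logits, final hidden states, attention maps).

        ``logits`` has shape (B, T, vocab); logits at position t depend only on
        positions <= t.  Attention maps (one (B, H, T, T) array per layer) are
        collected only when requested.
        """
        x = self.drop(self.embed(ids, prop_onehot, prop_values), rng)
        maps: list[np.ndarray] = []
        for block in self.blocks:
            x, weights = block(x, rng)
            if collect_attention:
                maps.append(weights.data)
        hidden = self.ln_f(x)
        return self.head(hidden), hidden, maps

    def __call__(self, ids, **kwargs):
        return self.forward(ids, **kwargs)

    def map_sequence_embedding(self, hidden: Tensor, mask: np.ndarray) -> Tensor:
        """Pool final hidden states over non-PAD positions and project to the
        alignment space (the z^B side of the alignment loss)."""
        mask = np.asarray(mask, dtype=np.float64)
        counts = mask.sum(axis=1)
        if np.any(counts == 0):
            raise ValueError("cannot pool a fully masked sequence")
        pooled = (hidden * Tensor(mask[..., None])).sum(axis=1) / Tensor(counts[:, None])
        return self.mapper(pooled)
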