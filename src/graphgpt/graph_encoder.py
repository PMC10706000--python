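"""Two-layer multi-head graph-attention encoder for molecular graphs.

For a node i with neighborhood N_i (self-loop included), each head computes
unnormalized scores e_ij = LeakyReLU(a^T [W h_i || W h_j]), normalizes them
with a softmax over N_i, aggregates the projected neighbor features with the
resulting coefficients and applies a sigmoid; the K head outputs are
concatenated.  After the second layer a ReLU and a global max pool over
nodes yield a fixed-length, permutation-invariant molecule embedding.

The encoder participates only in the training objective (it regularizes the
sequence representation through the redundancy-reduction alignment loss);
generation never constructs a molecular graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import NODE_FEATURE_DIM, MolecularGraph
from .nn import Dropout, Module, Tensor, concat, softmax, stack

_NEG_INF = -1e9


@dataclass
class GraphEncoderConfig:
    in_dim: int = NODE_FEATURE_DIM
    hidden_dim: int = 16  # per head, first layer
    out_dim: int = 64  # alignment-space dim d; must match the sequence mapper
    heads: int = 4  # first layer; second layer is single-head
    dropout: float = 0.1
    negative_slope: float = 0.2


class GATHead(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, negative_slope: float):
        super().__init__()
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.W = Tensor(rng.normal(0.0, scale, size=(d_in, d_out)), requires_grad=True)
        self.a_src = Tensor(rng.normal(0.0, scale, size=(d_out,)), requires_grad=True)
        self.a_dst = Tensor(rng.normal(0.0, scale, size=(d_out,)), requires_grad=True)
        self.negative_slope = negative_slope

    def attention(self, h: Tensor, adj: np.ndarray) -> tuple[Tensor, Tensor]:
        """Return (row-stochastic coefficients over neighborhoods, W h)."""
        wh = h @ self.W  # (N, d_out)
        f_src = (wh @ self.a_src.reshape(-1, 1)).reshape(-1, 1)  # score of i as query
        f_dst = (wh @ self.a_dst.reshape(-1, 1)).reshape(1, -1)  # score of j as key
        e = (f_src + f_dst).leaky_relu(self.negative_slope)  # e[i, j]
        masked = e + Tensor(np.where(adj > 0, 0.0, _NEG_INF))
        return softmax(masked, axis=1), wh

    def __call__(self, h: Tensor, adj: np.ndarray) -> Tensor:
        coeff, wh = self.attention(h, adj)
        return (coeff @ wh).sigmoid()


class GATLayer(Module):
    """K attention heads whose sigmoid-activated outputs are concatenated."""

    def __init__(
        self,
        d_in: int,
        d_out: int,
        heads: int,
        rng: np.random.Generator,
        negative_slope: float = 0.2,
        dropout: float = 0.1,
    ):
        super().__init__()
        self.heads = [GATHead(d_in, d_out, rng, negative_slope) for _ in range(heads)]
        self.drop = Dropout(dropout)

    def __call__(self, h: Tensor, adj: np.ndarray, rng: np.random.Generator | None = None) -> Tensor:
        out = concat([head(h, adj) for head in self.heads], axis=1)
        return self.drop(out, rng)

    def attention_coefficients(self, h: Tensor, adj: np.ndarray) -> list[np.ndarray]:
        """Per-head dense coefficient matrices (rows sum to 1 on neighborhoods)."""
        return [head.attention(h, adj)[0].data for head in self.heads]


class GraphEncoder(Module):
    def __init__(self, config: GraphEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.layer1 = GATLayer(
            config.in_dim,
            config.hidden_dim,
            config.heads,
            rng,
            config.negative_slope,
            config.dropout,
        )
        self.layer2 = GATLayer(
            config.hidden_dim * config.heads,
            config.out_dim,
            1,
            rng,
            config.negative_slope,
            config.dropout,
        )

    def __call__(self, graph: MolecularGraph, rng: np.random.Generator | None = None) -> Tensor:
        adj = graph.adjacency(self_loops=True)
        h = Tensor(graph.node_features)
        h = self.layer1(h, adj, rng)
        h = self.layer2(h, adj, rng)
        return h.relu().max(axis=0)  # global max pool -> (out_dim,)

    def encode_graph(self, graph: MolecularGraph) -> np.ndarray:
        """Deterministic embedding (eval mode, no dropout)."""
        mode = self.training
        self.eval()
        try:
            return self(graph).data
        finally:
            self.train(mode)

    def encode_batch(self, graphs: list[MolecularGraph], rng: np.random.Generator | None = None) -> Tensor:
        return stack([self(g, rng) for g in graphs], axis=0)
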