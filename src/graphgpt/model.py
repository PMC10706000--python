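"""The combined model: causal SMILES decoder aligned with a graph encoder.

During training the two views of each molecule — its heavy-atom graph pushed
through the GAT encoder (z^A) and its token sequence pooled through the
decoder's mapper (z^B) — are driven toward redundancy-free agreement by the
Barlow Twins term, while the decoder itself learns next-token prediction.
At inference only the decoder runs; no molecular graph is ever built.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from .chem import MolecularGraph
from .graph_encoder import GraphEncoder, GraphEncoderConfig
from .losses import BarlowTwinsConfig, LossBreakdown, barlow_twins_loss, cross_correlation, generation_loss
from .nn import Module, Tensor
from .sequence_model import MiniGPT, MiniGPTConfig
from .tokenizer import TokenSequence, Vocabulary


@dataclass
class PropertyStats:
    """Per-property normalization applied to condition scalars before the
    affine slot embedding (targets are O(1) inputs to the model)."""

    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    def normalize(self, prop: str, value: float) -> float:
        if prop not in self.mean:
            return float(value)
        return (float(value) - self.mean[prop]) / max(self.std[prop], 1e-8)


class GraphGPT(Module):
    def __init__(
        self,
        vocab: Vocabulary,
        gpt_config: MiniGPTConfig,
        graph_config: GraphEncoderConfig | None,
        bt_config: BarlowTwinsConfig,
        property_schema: tuple[str, ...],
        scaffold_conditioning: bool,
        prop_stats: PropertyStats,
        seed: int = 0,
    ):
        super().__init__()
        self.vocab = vocab
        self.gpt_config = gpt_config
        self.graph_config = graph_config
        self.bt_config = bt_config
        self.property_schema = tuple(property_schema)
        self.scaffold_conditioning = scaffold_conditioning
        self.prop_stats = prop_stats
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.gpt = MiniGPT(gpt_config, rng)
        self.graph_encoder = GraphEncoder(graph_config, rng) if graph_config else None

    # ------------------------------------------------------------- batching
    def assemble_batch(self, sequences: list[TokenSequence]) -> dict[str, np.ndarray]:
        """Stack sequences into model inputs, cropped to the longest content."""
        t_max = max(int(np.max(np.nonzero(s.mask)[0])) + 2 for s in sequences)
        t_max = min(t_max, self.gpt_config.max_len)
        b = len(sequences)
        p = len(self.property_schema)
        ids = np.stack([s.ids[:t_max] for s in sequences])
        pool_mask = np.stack([s.mask[:t_max] for s in sequences])
        loss_mask = np.stack([s.loss_positions()[:t_max] for s in sequences])
        targets = np.full_like(ids, self.vocab.pad_id)
        targets[:, :-1] = ids[:, 1:]
        loss_mask[:, -1] = False  # final position has no successor to predict
        prop_onehot = np.zeros((b, t_max, p))
        prop_values = np.zeros((b, t_max))
        slot_index = {name: i for i, name in enumerate(self.property_schema)}
        for row, seq in enumerate(sequences):
            for pos, name, value in seq.prop_slots:
                prop_onehot[row, pos, slot_index[name]] = 1.0
                prop_values[row, pos] = self.prop_stats.normalize(name, value)
        return {
            "ids": ids,
            "targets": targets,
            "loss_mask": loss_mask,
            "pool_mask": pool_mask,
            "prop_onehot": prop_onehot,
            "prop_values": prop_values,
        }

    # --------------------------------------------------------------- losses
    def compute_losses(
        self,
        sequences: list[TokenSequence],
        graphs: list[MolecularGraph] | None,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, LossBreakdown]:
        """Total loss L = L_BT + L_ground for one batch (Tensor for backprop,
        plus a float breakdown for logging).  ``graphs`` is None when the
        graph encoder is disabled, in which case L_BT is identically 0."""
        batch = self.assemble_batch(sequences)
        logits, hidden, _ = self.gpt.forward(
            batch["ids"],
            prop_onehot=batch["prop_onehot"] if self.property_schema else None,
            prop_values=batch["prop_values"] if self.property_schema else None,
            rng=rng,
        )
        l_ground = generation_loss(logits, batch["targets"], batch["loss_mask"])
        if self.graph_encoder is not None and graphs is not None:
            za = self.graph_encoder.encode_batch(graphs, rng)
            zb = self.gpt.map_sequence_embedding(hidden, batch["pool_mask"])
            c = cross_correlation(za, zb, standardize=self.bt_config.standardize, eps=1e-8)
            l_bt = barlow_twins_loss(c, self.bt_config.lam)
            total = l_bt + l_ground
            breakdown = LossBreakdown(
                total=float(total.data), alignment=float(l_bt.data), generation=float(l_ground.data)
            )
        else:
            total = l_ground
            breakdown = LossBreakdown(
                total=float(total.data), alignment=0.0, generation=float(l_ground.data)
            )
        return total, breakdown

    # ----------------------------------------------------------- checkpoint
    def save(self, path: str) -> None:
        os.makedirs(path, exist_ok=True)
        np.savez(os.path.join(path, "weights.npz"), **self.state_dict())
        manifest = {
            "gpt_config": asdict(self.gpt_config),
            "graph_config": asdict(self.graph_config) if self.graph_config else None,
            "bt_config": asdict(self.bt_config),
            "property_schema": list(self.property_schema),
            "scaffold_conditioning": self.scaffold_conditioning,
            "prop_stats": asdict(self.prop_stats),
            "seed": self.seed,
        }
        with open(os.path.join(path, "config.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        with open(os.path.join(path, "vocab.json"), "w") as fh:
            fh.write(self.vocab.to_json())

    @classmethod
    def load(cls, path: str) -> "GraphGPT":
        with open(os.path.join(path, "config.json")) as fh:
            manifest = json.load(fh)
        with open(os.path.join(path, "vocab.json")) as fh:
            vocab = Vocabulary.from_json(fh.read())
        model = cls(
            vocab=vocab,
            gpt_config=MiniGPTConfig(**manifest["gpt_config"]),
            graph_config=(
                GraphEncoderConfig(**manifest["graph_config"])
                if manifest["graph_config"]
                else None
            ),
            bt_config=BarlowTwinsConfig(**manifest["bt_config"]),
            property_schema=tuple(manifest["property_schema"]),
            scaffold_conditioning=manifest["scaffold_conditioning"],
            prop_stats=PropertyStats(**manifest["prop_stats"]),
            seed=manifest["seed"],
        )
        with np.load(os.path.join(path, "weights.npz")) as weights:
            model.load_state_dict({k: weights[k] for k in weights.files})
        return model
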