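"""End-to-end training loop with ablation switches and deterministic seeding.

The graph encoder is a training-time device only: with
``use_graph_encoder=False`` no molecular graph is ever constructed and the
alignment-loss column of the log is identically zero.  A single ``seed``
drives initialization, shuffling and dropout, so two runs with the same seed
and data produce identical logs and checkpoints.
"""

from __future__ import annotations

import csv
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .chem import MoleculeRecord, mol_to_graph
from .errors import ConfigurationError, LengthError
from .graph_encoder import GraphEncoderConfig
from .losses import BarlowTwinsConfig
from .model import GraphGPT, PropertyStats
from .nn import AdamW, cosine_warmup_lr
from .sequence_model import MiniGPTConfig
from .tokenizer import GenerationCondition, build_vocab, encode

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 256  # 16 at toy scale
    lr: float = 6e-4
    weight_decay: float = 0.01
    seed: int = 0
    decoder_layers: int = 8  # 4 | 8 | 12 for the depth ablation
    n_heads: int = 8
    d_model: int = 256
    max_len: int = 100
    dropout: float = 0.1
    alignment_dim: int = 64
    use_graph_encoder: bool = True
    graph_hidden_dim: int = 16
    graph_heads: int = 4
    lam: float = 0.005
    standardize_embeddings: bool = True
    condition_properties: tuple[str, ...] = ()
    condition_scaffold: bool = False
    grad_clip: float = 1.0

    def __post_init__(self) -> None:
        if self.decoder_layers < 1:
            raise ConfigurationError("decoder_layers must be >= 1")
        if self.standardize_embeddings and self.use_graph_encoder and self.batch_size < 2:
            raise ConfigurationError("embedding standardization needs batch_size >= 2")
        self.condition_properties = tuple(self.condition_properties)

    @classmethod
    def from_yaml(cls, path: str) -> "TrainConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class TrainResult:
    model: GraphGPT
    log: list[dict]  # rows: step, epoch, loss, loss_bt, loss_ground
    skipped_overlength: int
    initial_generation_loss: float
    final_generation_loss: float


def _build_model(records: list[MoleculeRecord], config: TrainConfig) -> GraphGPT:
    corpus = [r.smiles for r in records]
    if config.condition_scaffold:
        corpus += [r.scaffold for r in records if r.scaffold]
    vocab = build_vocab(corpus, properties=config.condition_properties)
    stats = PropertyStats()
    for prop in config.condition_properties:
        values = np.array([r.properties[prop] for r in records], dtype=float)
        stats.mean[prop] = float(values.mean())
        stats.std[prop] = float(max(values.std(), 1e-8))
    gpt_config = MiniGPTConfig(
        vocab_size=vocab.size,
        n_layers=config.decoder_layers,
        n_heads=config.n_heads,
        d_model=config.d_model,
        max_len=config.max_len,
        dropout=config.dropout,
        alignment_dim=config.alignment_dim,
        n_properties=len(config.condition_properties),
    )
    graph_config = (
        GraphEncoderConfig(
            hidden_dim=config.graph_hidden_dim,
            out_dim=config.alignment_dim,
            heads=config.graph_heads,
            dropout=config.dropout,
        )
        if config.use_graph_encoder
        else None
    )
    return GraphGPT(
        vocab=vocab,
        gpt_config=gpt_config,
        graph_config=graph_config,
        bt_config=BarlowTwinsConfig(lam=config.lam, standardize=config.standardize_embeddings),
        property_schema=config.condition_properties,
        scaffold_conditioning=config.condition_scaffold,
        prop_stats=stats,
        seed=config.seed,
    )


def record_condition(record: MoleculeRecord, config: TrainConfig) -> GenerationCondition:
    """The training-time condition of a record: its own property values and,
    when scaffold conditioning is on, its own scaffold."""
    return GenerationCondition(
        property_targets={p: record.properties[p] for p in config.condition_properties},
        scaffold=record.scaffold if (config.condition_scaffold and record.scaffold) else None,
    )


def train(
    dataset: list[MoleculeRecord],
    config: TrainConfig,
    out_dir: str | None = None,
) -> TrainResult:
    """Train on a dataset of records; returns the model and per-step loss log."""
    if not dataset:
        raise ConfigurationError("training dataset is empty")
    model = _build_model(dataset, config)
    model.train()

    sequences, kept_records = [], []
    skipped = 0
    for record in dataset:
        try:
            seq = encode(record, record_condition(record, config), model.vocab, config.max_len)
        except LengthError:
            skipped += 1
            continue
        sequences.append(seq)
        kept_records.append(record)
    if skipped:
        logger.warning("skipped %d over-length molecules", skipped)
    if not sequences:
        raise ConfigurationError("no molecule fits within max_len")

    graph_cache = (
        {i: mol_to_graph(r.smiles) for i, r in enumerate(kept_records)}
        if config.use_graph_encoder
        else None
    )

    rng = np.random.default_rng(config.seed)
    dropout_rng = np.random.default_rng(rng.integers(2**31))
    shuffle_rng = np.random.default_rng(rng.integers(2**31))

    optimizer = AdamW(
        model.named_parameters(), lr=config.lr, weight_decay=config.weight_decay
    )
    n = len(sequences)
    steps_per_epoch = max(1, (n + config.batch_size - 1) // config.batch_size)
    total_steps = steps_per_epoch * config.epochs

    log: list[dict] = []
    step = 0
    initial_ground = final_ground = float("nan")
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if (
                config.use_graph_encoder
                and config.standardize_embeddings
                and len(idx) < 2
            ):
                continue  # a 1-element tail batch cannot be standardized
            batch_seqs = [sequences[i] for i in idx]
            batch_graphs = [graph_cache[i] for i in idx] if graph_cache else None
            model.zero_grad()
            total, breakdown = model.compute_losses(batch_seqs, batch_graphs, dropout_rng)
            if not np.isfinite(total.data):
                raise RuntimeError(
                    f"training diverged at step {step}: loss={float(total.data)!r} "
                    f"(L_BT={breakdown.alignment}, L_ground={breakdown.generation})"
                )
            total.backward()
            if config.grad_clip:
                _clip_gradients(model, config.grad_clip)
            optimizer.step(lr=cosine_warmup_lr(step, total_steps, config.lr))
            if step == 0:
                initial_ground = breakdown.generation
            final_ground = breakdown.generation
            log.append(
                {
                    "step": step,
                    "epoch": epoch,
                    "loss": breakdown.total,
                    "loss_bt": breakdown.alignment,
                    "loss_ground": breakdown.generation,
                }
            )
            step += 1

    model.eval()
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        model.save(out_dir)
        write_log(log, os.path.join(out_dir, "train_log.csv"))
    return TrainResult(
        model=model,
        log=log,
        skipped_overlength=skipped,
        initial_generation_loss=initial_ground,
        final_generation_loss=final_ground,
    )


def _clip_gradients(model: GraphGPT, max_norm: float) -> None:
    params = model.parameters()
    total = np.sqrt(sum(float((p.grad**2).sum()) for p in params if p.grad is not None))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def write_log(log: list[dict], path: str) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["step", "epoch", "loss", "loss_bt", "loss_ground"])
        writer.writeheader()
        writer.writerows(log)
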