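"""Autoregressive sampling under a generation condition.

Decoding starts from the encoded condition prefix followed by BOS and
proceeds token by token (multinomial at the given temperature, or greedy at
temperature 0) until EOS or the model's maximum length.  The graph encoder
is never touched here — conditioning information flows only through the
prefix the decoder was trained on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .model import GraphGPT
from .nn import Tensor
from .tokenizer import GenerationCondition, decode_flagged, encode_prefix, tokenize


@dataclass
class SampleBatch:
    smiles: list[str]  # raw generated strings, possibly invalid
    condition: GenerationCondition
    seed: int
    temperature: float
    well_formed: list[bool] = field(default_factory=list)  # BOS..EOS structure seen


def sample(
    model: GraphGPT,
    n: int,
    condition: GenerationCondition | None = None,
    temperature: float = 1.0,
    seed: int = 0,
    top_k: int | None = None,
    batch_size: int = 128,
) -> SampleBatch:
    """Draw ``n`` molecules from the model under ``condition``."""
    condition = condition or GenerationCondition()
    for prop in condition.property_targets:
        if prop not in model.property_schema:
            raise ConfigurationError(
                f"property {prop!r} is not in the trained condition schema "
                f"{model.property_schema}"
            )
    if condition.scaffold and not model.scaffold_conditioning:
        raise ConfigurationError("model was not trained with scaffold conditioning")
    if temperature < 0:
        raise ConfigurationError("temperature must be >= 0")
    model.eval()
    vocab = model.vocab
    max_len = model.gpt_config.max_len
    prefix = encode_prefix(condition, vocab, max_len=max_len)
    rng = np.random.default_rng(seed)

    all_ids: list[np.ndarray] = []
    remaining = int(n)
    while remaining > 0:
        b = min(batch_size, remaining)
        all_ids.extend(_sample_block(model, b, prefix, temperature, top_k, rng))
        remaining -= b

    smiles, flags = [], []
    for ids in all_ids:
        s, ok = decode_flagged(ids, vocab)
        smiles.append(s)
        flags.append(ok)
    return SampleBatch(
        smiles=smiles, condition=condition, seed=seed, temperature=temperature, well_formed=flags
    )


def _sample_block(model, b, prefix, temperature, top_k, rng):
    vocab = model.vocab
    max_len = model.gpt_config.max_len
    p = len(model.property_schema)
    slot_index = {name: i for i, name in enumerate(model.property_schema)}

    start = prefix.length + 1
    ids = np.full((b, max_len), vocab.pad_id, dtype=np.int64)
    ids[:, : prefix.length] = prefix.ids[: prefix.length]
    ids[:, prefix.length] = vocab.bos_id
    prop_onehot = np.zeros((b, max_len, p))
    prop_values = np.zeros((b, max_len))
    for pos, name, value in prefix.prop_slots:
        prop_onehot[:, pos, slot_index[name]] = 1.0
        prop_values[:, pos] = model.prop_stats.normalize(name, value)

    finished = np.zeros(b, dtype=bool)
    for t in range(start, max_len):
        logits, _, _ = model.gpt.forward(
            ids[:, :t],
            prop_onehot=prop_onehot[:, :t] if p else None,
            prop_values=prop_values[:, :t] if p else None,
        )
        last = logits.data[:, -1, :].copy()  # (b, vocab)
        last[:, vocab.pad_id] = -np.inf  # PAD is never a legal continuation
        if temperature == 0:
            nxt = last.argmax(axis=1)
        else:
            scaled = last / temperature
            if top_k is not None:
                kth = np.partition(scaled, -top_k, axis=1)[:, -top_k][:, None]
                scaled = np.where(scaled < kth, -np.inf, scaled)
            scaled = scaled - scaled.max(axis=1, keepdims=True)
            probs = np.exp(scaled)
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random((b, 1))
            nxt = (probs.cumsum(axis=1) < u).sum(axis=1)
        nxt = np.where(finished, vocab.pad_id, nxt)
        ids[:, t] = nxt
        finished |= nxt == vocab.eos_id
        if finished.all():
            break
    return [ids[i] for i in range(b)]


@dataclass
class AttentionMaps:
    tokens: list[str]
    maps: list[np.ndarray]  # one (n_heads, T, T) array per layer

    def to_jsonable(self) -> dict:
        return {"tokens": self.tokens, "maps": [m.tolist() for m in self.maps]}


def attention_maps(model: GraphGPT, smiles: str) -> AttentionMaps:
    """Per-layer, per-head causal attention over the tokens of ``smiles``.

    Each row sums to 1 over the visible (non-future) positions; strictly
    upper-triangular entries are exactly 0.
    """
    tokens = tokenize(smiles)
    if len(tokens) > model.gpt_config.max_len:
        from .errors import LengthError

        raise LengthError(f"{len(tokens)} tokens exceed max_len {model.gpt_config.max_len}")
    ids = np.array([[model.vocab[t] for t in tokens]])
    model.eval()
    _, _, maps = model.gpt.forward(ids, collect_attention=True)
    return AttentionMaps(tokens=tokens, maps=[m[0] for m in maps])
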