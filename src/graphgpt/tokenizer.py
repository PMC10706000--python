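"""SMILES tokenization, vocabulary and condition-prefixed sequence encoding.

A sequence presented to the decoder is laid out as

    [property slots][SEP][scaffold tokens][SEP][BOS][molecule tokens][EOS][PAD...]

where segments absent from the condition are omitted together with their SEP.
Property slots are reserved marker tokens (one per conditioned property); the
sequence model replaces their embeddings with an affine map of the scalar
target value, so targets are injected continuously rather than binned into a
token alphabet.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

import numpy as np

from .chem import PROPERTY_NAMES, MoleculeRecord
from .errors import ConfigurationError, LengthError, TokenizationError

MAX_LEN = 100

PAD, BOS, EOS, SEP = "<pad>", "<bos>", "<eos>", "<sep>"
SPECIALS = (PAD, BOS, EOS, SEP)

_PROP_TOKEN = {name: f"<{name}>" for name in PROPERTY_NAMES}

# Bracket atoms, two-letter halogens, %nn ring closures, then single-character
# atoms / bonds / branches / ring digits.
_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|%\d{2}|[BCNOPSFIbcnops]|[0-9]|[=#\-\+\(\)\\/\.~:\*\$@])"
)


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into tokens; concatenation reproduces the input."""
    tokens: list[str] = []
    pos = 0
    while pos < len(smiles):
        match = _TOKEN_RE.match(smiles, pos)
        if match is None:
            raise TokenizationError(
                f"character {smiles[pos]!r} at position {pos} of {smiles!r} "
                "is outside the SMILES alphabet"
            )
        tokens.append(match.group(0))
        pos = match.end()
    return tokens


@dataclass
class Vocabulary:
    token_to_id: dict[str, int]
    specials: dict[str, int]
    property_slots: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.token_to_id)

    def __post_init__(self) -> None:
        self.id_to_token = {i: t for t, i in self.token_to_id.items()}
        if len(self.id_to_token) != len(self.token_to_id):
            raise ConfigurationError("vocabulary mapping is not a bijection")

    def __getitem__(self, token: str) -> int:
        try:
            return self.token_to_id[token]
        except KeyError:
            raise ConfigurationError(f"token {token!r} not in vocabulary") from None

    @property
    def pad_id(self) -> int:
        return self.specials[PAD]

    @property
    def bos_id(self) -> int:
        return self.specials[BOS]

    @property
    def eos_id(self) -> int:
        return self.specials[EOS]

    @property
    def sep_id(self) -> int:
        return self.specials[SEP]

    # ------------------------------------------------------------- round trip
    def to_json(self) -> str:
        return json.dumps(
            {
                "token_to_id": self.token_to_id,
                "specials": self.specials,
                "property_slots": self.property_slots,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, payload: str) -> "Vocabulary":
        obj = json.loads(payload)
        return cls(
            token_to_id=dict(obj["token_to_id"]),
            specials=dict(obj["specials"]),
            property_slots=dict(obj.get("property_slots", {})),
        )


def build_vocab(corpus: list[str], properties: tuple[str, ...] = ()) -> Vocabulary:
    """Build a deterministic vocabulary: specials, property-slot markers for
    the conditioned properties, then the corpus tokens in sorted order."""
    if not corpus:
        raise ConfigurationError("cannot build a vocabulary from an empty corpus")
    for prop in properties:
        if prop not in PROPERTY_NAMES:
            raise ConfigurationError(f"unknown conditioning property {prop!r}")
    tokens: set[str] = set()
    for smiles in corpus:
        tokens.update(tokenize(smiles))
    token_to_id: dict[str, int] = {}
    for special in SPECIALS:
        token_to_id[special] = len(token_to_id)
    slots: dict[str, int] = {}
    for prop in sorted(properties, key=PROPERTY_NAMES.index):
        slots[prop] = len(token_to_id)
        token_to_id[_PROP_TOKEN[prop]] = len(token_to_id)
    for token in sorted(tokens):
        token_to_id[token] = len(token_to_id)
    return Vocabulary(
        token_to_id=token_to_id,
        specials={s: token_to_id[s] for s in SPECIALS},
        property_slots=slots,
    )


@dataclass
class GenerationCondition:
    """Optional property targets and/or a scaffold steering generation."""

    property_targets: dict[str, float] = field(default_factory=dict)
    scaffold: str | None = None

    def __post_init__(self) -> None:
        for prop in self.property_targets:
            if prop not in PROPERTY_NAMES:
                raise ConfigurationError(f"unknown conditioning property {prop!r}")

    def ordered_properties(self) -> list[str]:
        return sorted(self.property_targets, key=PROPERTY_NAMES.index)


@dataclass
class TokenSequence:
    """Fixed-length id sequence with its mask and structural annotations."""

    ids: np.ndarray  # (max_len,) int
    mask: np.ndarray  # (max_len,) bool, true on non-PAD positions
    smiles_span: tuple[int, int]  # [start, end) of the molecule tokens
    prop_slots: list[tuple[int, str, float]] = field(default_factory=list)
    # (position, property name, scalar target)

    @property
    def bos_position(self) -> int:
        return self.smiles_span[0] - 1

    def loss_positions(self) -> np.ndarray:
        """Positions whose next-token predictions enter the cross-entropy:
        BOS through the last molecule token (each predicts its successor,
        ending with EOS).  Condition-prefix positions are excluded."""
        start, end = self.smiles_span
        out = np.zeros(len(self.ids), dtype=bool)
        out[start - 1 : end] = True
        return out


def encode(
    record: MoleculeRecord | str,
    condition: GenerationCondition,
    vocab: Vocabulary,
    max_len: int = MAX_LEN,
) -> TokenSequence:
    """Encode a molecule with its condition prefix into a fixed-length sequence."""
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    prefix = encode_prefix(condition, vocab, max_len=max_len)
    mol_tokens = tokenize(smiles)
    ids = list(prefix.ids[: prefix.length])
    start = len(ids) + 1  # after BOS
    ids.append(vocab.bos_id)
    ids.extend(vocab[t] for t in mol_tokens)
    ids.append(vocab.eos_id)
    if len(ids) > max_len:
        raise LengthError(
            f"encoded length {len(ids)} exceeds max_len={max_len} for {smiles!r}"
        )
    end = start + len(mol_tokens)
    full = np.full(max_len, vocab.pad_id, dtype=np.int64)
    full[: len(ids)] = ids
    mask = np.zeros(max_len, dtype=bool)
    mask[: len(ids)] = True
    return TokenSequence(ids=full, mask=mask, smiles_span=(start, end), prop_slots=prefix.prop_slots)


@dataclass
class ConditionPrefix:
    ids: np.ndarray
    length: int
    prop_slots: list[tuple[int, str, float]]


def encode_prefix(
    condition: GenerationCondition, vocab: Vocabulary, max_len: int = MAX_LEN
) -> ConditionPrefix:
    """Encode only the condition prefix (used at sampling time, before BOS)."""
    ids: list[int] = []
    prop_slots: list[tuple[int, str, float]] = []
    props = condition.ordered_properties()
    if props:
        for prop in props:
            if prop not in vocab.property_slots:
                raise ConfigurationError(
                    f"property {prop!r} was not part of the trained condition schema"
                )
            prop_slots.append((len(ids), prop, float(condition.property_targets[prop])))
            ids.append(vocab.property_slots[prop])
        ids.append(vocab.sep_id)
    if condition.scaffold:
        ids.extend(vocab[t] for t in tokenize(condition.scaffold))
        ids.append(vocab.sep_id)
    if len(ids) >= max_len - 2:
        raise LengthError(f"condition prefix of length {len(ids)} leaves no room")
    arr = np.full(max_len, vocab.pad_id, dtype=np.int64)
    arr[: len(ids)] = ids
    return ConditionPrefix(ids=arr, length=len(ids), prop_slots=prop_slots)


def decode_flagged(ids, vocab: Vocabulary) -> tuple[str, bool]:
    """Decode generated ids back to a SMILES string.

    Returns ``(smiles, well_formed)``: tokens strictly between BOS and the
    first EOS after it, concatenated.  Missing BOS yields ``("", False)``;
    missing EOS yields the truncated string flagged False.
    """
    ids = [int(i) for i in np.asarray(ids).ravel()]
    try:
        bos_at = ids.index(vocab.bos_id)
    except ValueError:
        return "", False
    out: list[str] = []
    for token_id in ids[bos_at + 1 :]:
        if token_id == vocab.eos_id:
            return "".join(out), True
        if token_id in (vocab.pad_id, vocab.bos_id, vocab.sep_id):
            continue
        token = vocab.id_to_token.get(token_id)
        if token is None or token.startswith("<"):
            continue
        out.append(token)
    return "".join(out), False


def decode(ids, vocab: Vocabulary) -> str:
    return decode_flagged(ids, vocab)[0]
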