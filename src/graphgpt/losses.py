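"""The combined training objective L = L_BT + L_ground.

L_BT is a Barlow Twins redundancy-reduction loss on the cross-correlation
matrix between graph-encoder embeddings z^A and sequence-mapper embeddings
z^B computed over a batch; it pushes the matrix toward the identity (each
dimension of the two views agrees, distinct dimensions decorrelate).
L_ground is the usual next-token cross-entropy under teacher forcing.
The two terms are summed unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, log_softmax

DEFAULT_LAMBDA = 0.005


@dataclass
class BarlowTwinsConfig:
    lam: float = DEFAULT_LAMBDA  # off-diagonal weight
    standardize: bool = True  # per-dimension batch standardization first

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")


@dataclass
class LossBreakdown:
    total: float
    alignment: float  # L_BT
    generation: float  # L_ground


def _as_tensor(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


def cross_correlation(za, zb, standardize: bool = True, eps: float = 0.0):
    """Cross-correlation matrix between two batches of embeddings.

    C_ij = sum_b z_bi^A z_bj^B / (||z_i^A|| ||z_j^B||), the norms taken over
    the batch.  With ``standardize`` each dimension is first shifted to zero
    mean and unit variance across the batch (the convention of the cited
    redundancy-reduction method); without it the formula is applied to the
    raw embeddings.  (Only centering is applied: the norm denominators make
    C invariant to per-dimension rescaling, so a variance division would
    cancel.)  Entries are bounded in [-1, 1] by Cauchy–Schwarz.

    ``eps`` > 0 smooths the norm denominators so dimensions that are constant
    across a batch contribute zero correlation instead of raising; with the
    default 0 a zero-norm dimension is an error naming the dimension.
    """
    za_t, a_tensor = _as_tensor(za)
    zb_t, b_tensor = _as_tensor(zb)
    if za_t.shape != zb_t.shape or za_t.ndim != 2:
        raise ValueError("embeddings must be two matching (batch, dim) matrices")
    if standardize:
        if za_t.shape[0] < 2:
            raise ValueError("standardization needs a batch of at least 2")
        za_t = za_t - za_t.mean(axis=0, keepdims=True)
        zb_t = zb_t - zb_t.mean(axis=0, keepdims=True)
    for name, z in (("A", za_t), ("B", zb_t)):
        norms = np.sqrt((z.data**2).sum(axis=0))
        dead = np.nonzero(norms <= 1e-12)[0]
        if dead.size and eps == 0.0:
            raise ValueError(
                f"zero-norm embedding dimension(s) {dead.tolist()} on side {name}"
            )
    na = ((za_t**2).sum(axis=0) + eps).sqrt()
    nb = ((zb_t**2).sum(axis=0) + eps).sqrt()
    c = (za_t.swapaxes(0, 1) @ zb_t) / (na.reshape(-1, 1) * nb.reshape(1, -1))
    return c if (a_tensor or b_tensor) else c.data


def barlow_twins_loss(c, lam: float = DEFAULT_LAMBDA):
    """sum_i (1 - C_ii)^2 + lambda * sum_{i != j} C_ij^2 (zero iff C = I)."""
    c_t, was_tensor = _as_tensor(c)
    if c_t.ndim != 2 or c_t.shape[0] != c_t.shape[1]:
        raise ValueError("C must be square")
    d = c_t.shape[0]
    eye = np.eye(d)
    diag = ((Tensor(np.ones(d)) - (c_t * Tensor(eye)).sum(axis=1)) ** 2).sum()
    off = ((c_t * Tensor(1.0 - eye)) ** 2).sum()
    loss = diag + lam * off
    return loss if was_tensor else float(loss.data)


def generation_loss(logits, targets, mask):
    """Mean next-token cross-entropy over unmasked positions.

    ``logits`` is (B, T, V) (or (T, V)), ``targets`` the left-shifted ids and
    ``mask`` marks the positions whose prediction counts (PAD and
    condition-prefix positions excluded).
    """
    logits_t, was_tensor = _as_tensor(logits)
    if logits_t.ndim == 2:
        logits_t = logits_t.reshape(1, *logits_t.shape)
        targets = np.asarray(targets).reshape(1, -1)
        mask = np.asarray(mask).reshape(1, -1)
    targets = np.asarray(targets, dtype=np.intp)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("all positions are masked out of the loss")
    b, t, v = logits_t.shape
    logp = log_softmax(logits_t, axis=-1)
    flat = logp.reshape(b * t, v)
    rows = np.nonzero(mask.reshape(-1))[0]
    picked = flat[(rows, targets.reshape(-1)[rows])]
    loss = -(picked.mean())
    return loss if was_tensor else float(loss.data)


def combine(alignment, generation) -> "LossBreakdown | Tensor":
    """Total loss L = L_BT + L_ground; Tensors stay Tensors for backprop."""
    if isinstance(alignment, Tensor) or isinstance(generation, Tensor):
        a, _ = _as_tensor(alignment)
        g, _ = _as_tensor(generation)
        return a + g
    return LossBreakdown(
        total=float(alignment) + float(generation),
        alignment=float(alignment),
        generation=float(generation),
    )
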