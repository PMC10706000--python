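"""Evaluation suite for generated molecule sets.

Covers the standard generative-chemistry metrics — validity / uniqueness /
novelty, internal diversity over Morgan-fingerprint Tanimoto similarity,
Fréchet distance between Gaussian fits of molecule features (with a
pluggable featurizer), a KL-divergence score over physicochemical
descriptors — plus the condition-deviation statistics (SD and MAD) used to
judge how tightly generated property values track their targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import scipy.linalg
from rdkit import Chem
from rdkit.Chem import Crippen, DataStructs, Descriptors, rdFingerprintGenerator, rdMolDescriptors

from .chem import PROPERTY_NAMES, canonicalize, compute_properties, is_valid
from .errors import ParseError

# ------------------------------------------------------------------- VUN
@dataclass
class GenerationReport:
    valid: float
    unique: float
    novelty: float
    n_total: int
    n_valid: int
    n_unique: int
    n_novel: int
    degenerate: bool = False  # a denominator was zero and reported as 0


def vun_report(generated: Sequence[str], training_canonical: set[str]) -> GenerationReport:
    """Validity, uniqueness and novelty of a generated set.

    valid = parseable fraction of all samples; unique = distinct canonical
    SMILES among the valid ones; novelty = fraction of those distinct
    molecules absent from the (pre-canonicalized) training set.
    """
    n_total = len(generated)
    canonical_valid: list[str] = []
    for smi in generated:
        if smi and is_valid(smi):
            canonical_valid.append(canonicalize(smi))
    n_valid = len(canonical_valid)
    distinct = set(canonical_valid)
    n_unique = len(distinct)
    novel = {s for s in distinct if s not in training_canonical}
    n_novel = len(novel)
    degenerate = n_total == 0 or n_valid == 0 or n_unique == 0
    return GenerationReport(
        valid=n_valid / n_total if n_total else 0.0,
        unique=n_unique / n_valid if n_valid else 0.0,
        novelty=n_novel / n_unique if n_unique else 0.0,
        n_total=n_total,
        n_valid=n_valid,
        n_unique=n_unique,
        n_novel=n_novel,
        degenerate=degenerate,
    )


# --------------------------------------------------------------- IntDiv
_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def _fingerprints(smiles: Sequence[str]):
    fps = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ParseError(f"invalid SMILES in diversity computation: {smi!r}")
        fps.append(_MORGAN.GetFingerprint(mol))
    return fps


def intdiv(smiles: Sequence[str], p: int = 1) -> float:
    """Internal diversity: 1 - ((1/|S|^2) sum Tanimoto^p)^(1/p) over ALL
    ordered pairs (self-pairs included), Morgan radius-2/2048-bit
    fingerprints.  The p-th root makes IntDiv2 <= IntDiv1, the convention of
    the MOSES benchmark tables."""
    if not smiles:
        raise ValueError("cannot compute internal diversity of an empty set")
    if p not in (1, 2):
        raise ValueError("p must be 1 or 2")
    fps = _fingerprints(smiles)
    n = len(fps)
    total = 0.0
    for fp in fps:
        sims = np.array(DataStructs.BulkTanimotoSimilarity(fp, fps))
        total += float((sims**p).sum())
    return 1.0 - (total / (n * n)) ** (1.0 / p)


# ------------------------------------------------------ Fréchet distance
@dataclass
class DistributionStats:
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance shape does not match the mean")
        if not np.allclose(self.cov, self.cov.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    @property
    def dim(self) -> int:
        return self.mean.size

    @classmethod
    def from_samples(cls, features: np.ndarray) -> "DistributionStats":
        features = np.asarray(features, dtype=float)
        cov = np.cov(features, rowvar=False)
        cov = np.atleast_2d((cov + cov.T) / 2.0)
        return cls(mean=features.mean(axis=0), cov=cov)


def frechet_distance(g: DistributionStats, d: DistributionStats) -> float:
    """||mu_G - mu_D||^2 + Tr(S_G + S_D - 2 (S_G S_D)^{1/2}).

    Tiny negative eigenvalues arising from the numerical matrix square root
    are clipped to zero; a covariance that is non-PSD beyond tolerance is an
    error.
    """
    if g.dim != d.dim:
        raise ValueError("distribution dimensions differ")
    for name, stats in (("G", g), ("D", d)):
        min_eig = float(np.linalg.eigvalsh(stats.cov).min())
        if min_eig < -1e-6:
            raise ValueError(f"covariance of {name} is not PSD (min eigenvalue {min_eig:.3g})")
    delta = g.mean - d.mean
    covmean = scipy.linalg.sqrtm(g.cov @ d.cov)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    fcd = float(delta @ delta + np.trace(g.cov + d.cov - 2.0 * covmean))
    return max(fcd, 0.0)


def guacamol_score(fcd: float) -> float:
    """Map a raw Fréchet distance to the (0, 1] benchmark score exp(-0.2 * FCD)."""
    return float(np.exp(-0.2 * fcd))


# --------------------------------------------------------- featurization
_KL_DESCRIPTORS: dict[str, Callable] = {
    "BertzCT": Descriptors.BertzCT,
    "MolWt": Descriptors.MolWt,
    "MolLogP": Crippen.MolLogP,
    "TPSA": Descriptors.TPSA,
    "NumHAcceptors": Descriptors.NumHAcceptors,
    "NumHDonors": Descriptors.NumHDonors,
    "NumRotatableBonds": Descriptors.NumRotatableBonds,
    "NumAromaticRings": rdMolDescriptors.CalcNumAromaticRings,
    "NumAliphaticRings": rdMolDescriptors.CalcNumAliphaticRings,
}


def descriptor_table(smiles: Sequence[str]) -> dict[str, np.ndarray]:
    """Per-descriptor value arrays over the valid molecules of ``smiles``."""
    columns: dict[str, list[float]] = {name: [] for name in _KL_DESCRIPTORS}
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi) if smi else None
        if mol is None:
            continue
        for name, fn in _KL_DESCRIPTORS.items():
            columns[name].append(float(fn(mol)))
    return {name: np.asarray(vals) for name, vals in columns.items()}


class DescriptorFeaturizer:
    """Physicochemical-descriptor feature vectors, standardized against a
    reference set.  This is the bundled default featurizer for the Fréchet
    distance; an activation-based featurizer can be plugged in instead via
    the ``featurizer`` argument of :func:`frechet_report`."""

    def __init__(self, reference_smiles: Sequence[str]):
        table = descriptor_table(reference_smiles)
        self.names = sorted(table)
        ref = np.column_stack([table[n] for n in self.names])
        self.mu = ref.mean(axis=0)
        self.sigma = np.maximum(ref.std(axis=0), 1e-8)

    def __call__(self, smiles: Sequence[str]) -> np.ndarray:
        table = descriptor_table(smiles)
        feats = np.column_stack([table[n] for n in self.names])
        return (feats - self.mu) / self.sigma


def frechet_report(
    generated: Sequence[str],
    reference: Sequence[str],
    featurizer: Callable[[Sequence[str]], np.ndarray] | None = None,
) -> dict[str, float]:
    """Fréchet distance between generated and reference molecule sets under
    the given featurizer (bundled descriptor featurizer by default), plus the
    exp(-0.2 FCD) benchmark score."""
    if featurizer is None:
        featurizer = DescriptorFeaturizer(reference)
    stats_g = DistributionStats.from_samples(featurizer(generated))
    stats_d = DistributionStats.from_samples(featurizer(reference))
    fcd = frechet_distance(stats_g, stats_d)
    return {"fcd": fcd, "score": guacamol_score(fcd)}


# ---------------------------------------------------------------- KL score
def kl_divergence_histogram(
    p_samples: np.ndarray,
    q_samples: np.ndarray,
    bins: int = 50,
    smoothing: float = 1e-10,
) -> float:
    """D_KL(P || Q) over a shared discretization whose bin edges come from
    the P (reference) side; samples outside the range are clipped into the
    edge bins and both histograms get additive smoothing."""
    p_samples = np.asarray(p_samples, dtype=float)
    q_samples = np.asarray(q_samples, dtype=float)
    if p_samples.size < 2 or q_samples.size < 2:
        raise ValueError("need at least 2 samples per side")
    lo, hi = float(p_samples.min()), float(p_samples.max())
    if hi <= lo:
        hi = lo + 1e-8
    edges = np.linspace(lo, hi, bins + 1)
    p_hist = np.histogram(np.clip(p_samples, lo, hi), bins=edges)[0].astype(float)
    q_hist = np.histogram(np.clip(q_samples, lo, hi), bins=edges)[0].astype(float)
    p = (p_hist + smoothing) / (p_hist + smoothing).sum()
    q = (q_hist + smoothing) / (q_hist + smoothing).sum()
    return float(np.sum(p * np.log(p / q)))


def kl_score(
    generated_descriptors: dict[str, np.ndarray],
    reference_descriptors: dict[str, np.ndarray],
    bins: int = 50,
) -> float:
    """S = (1/k) sum_i exp(-D_KL,i) over the shared descriptor set; equals 1
    exactly when every per-descriptor divergence is 0."""
    keys = sorted(reference_descriptors)
    if not keys or sorted(generated_descriptors) != keys:
        raise ValueError("descriptor sets must be non-empty and identical")
    divs = [
        kl_divergence_histogram(reference_descriptors[k], generated_descriptors[k], bins=bins)
        for k in keys
    ]
    return float(np.mean(np.exp(-np.asarray(divs))))


def kl_score_from_smiles(generated: Sequence[str], reference: Sequence[str]) -> float:
    return kl_score(descriptor_table(generated), descriptor_table(reference))


# ------------------------------------------------------ condition deviation
@dataclass
class ConditionDeviation:
    sd: dict[str, float] = field(default_factory=dict)  # about the sample mean
    mad: dict[str, float] = field(default_factory=dict)  # about the target
    n_valid: int = 0


def condition_deviation(
    generated: Sequence[str], targets: dict[str, float]
) -> ConditionDeviation:
    """SD (population, about the sample mean) and MAD (about the target) of
    each targeted property over the valid generated molecules."""
    for prop in targets:
        if prop not in PROPERTY_NAMES:
            raise ValueError(f"unknown property {prop!r}")
    values: dict[str, list[float]] = {p: [] for p in targets}
    n_valid = 0
    for smi in generated:
        if not smi or not is_valid(smi):
            continue
        n_valid += 1
        props = compute_properties(smi)
        for p in targets:
            values[p].append(props[p])
    if n_valid == 0:
        raise ValueError("no valid molecules to evaluate condition deviation on")
    out = ConditionDeviation(n_valid=n_valid)
    for p, target in targets.items():
        arr = np.asarray(values[p])
        out.sd[p] = float(arr.std())
        out.mad[p] = float(np.abs(arr - target).mean())
    return out
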