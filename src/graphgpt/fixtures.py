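"""Deterministic synthetic SMILES generation for tests and toy training.

Molecules are assembled from a closed fragment grammar — ring cores
(benzene, pyridine, cyclohexane) or short alkyl chains, decorated with
substituents drawn from a small pool (alkyl, hydroxyl, amino, halogen,
carbonyl) — so every output is valid by construction and property values
(notably TPSA, which the polar substituents sweep from 0 up past 80 Å²)
span a usable range.  The grammar emulates small drug-like molecules well
enough to exercise every pipeline stage; it does not reproduce the property
distributions of the large public training sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import MoleculeRecord, make_record
from .errors import ConfigurationError

CORES = {
    "benzene": "c1ccccc1",
    "pyridine": "c1ccncc1",
    "cyclohexane": "C1CCCCC1",
}

# substituent SMILES, attachment at atom 0, with heavy-atom counts
SUBSTITUENTS = {
    "methyl": "C",
    "ethyl": "CC",
    "propyl": "CCC",
    "hydroxyl": "O",
    "amino": "N",
    "fluoro": "F",
    "chloro": "Cl",
    "bromo": "Br",
    "acetyl": "C(=O)C",
    "carboxyl": "C(=O)O",
}


@dataclass
class SyntheticDatasetSpec:
    n: int
    seed: int = 0
    max_heavy_atoms: int = 16
    core_weights: dict[str, float] = field(
        default_factory=lambda: {"benzene": 0.45, "pyridine": 0.25, "cyclohexane": 0.2, "chain": 0.1}
    )
    substituent_weights: dict[str, float] = field(
        default_factory=lambda: {name: 1.0 for name in SUBSTITUENTS}
    )
    max_substituents: int = 3
    chain_lengths: tuple[int, int] = (1, 5)  # inclusive range for acyclic cores

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("n must be at least 1")
        if self.max_heavy_atoms < 1:
            raise ConfigurationError("max_heavy_atoms must be at least 1")


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    names = sorted(weights)
    probs = np.array([max(weights[n], 0.0) for n in names], dtype=float)
    if probs.sum() <= 0:
        raise ConfigurationError("all grammar weights are zero")
    return names[rng.choice(len(names), p=probs / probs.sum())]


def _attach(core: Chem.Mol, sub_smiles: str, core_atom: int) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(sub_smiles)
    combined = Chem.RWMol(Chem.CombineMols(core, frag))
    combined.AddBond(core_atom, core.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combined.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return out


def _one_molecule(spec: SyntheticDatasetSpec, rng: np.random.Generator) -> str:
    core_name = _weighted_choice(rng, spec.core_weights)
    if core_name == "chain" or spec.max_heavy_atoms < 6:
        lo, hi = spec.chain_lengths
        hi = min(hi, spec.max_heavy_atoms)
        length = int(rng.integers(lo, hi + 1))
        atoms = ["C"] * length
        if length >= 2 and rng.random() < 0.5:
            atoms[-1] = str(rng.choice(["O", "N", "C"]))
        smiles = "".join(atoms)
        return Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
    mol = Chem.MolFromSmiles(CORES[core_name])
    budget = spec.max_heavy_atoms - mol.GetNumAtoms()
    n_core = mol.GetNumAtoms()
    n_subs = int(rng.integers(0, spec.max_substituents + 1))
    for _ in range(n_subs):
        name = _weighted_choice(rng, spec.substituent_weights)
        frag_size = Chem.MolFromSmiles(SUBSTITUENTS[name]).GetNumAtoms()
        if frag_size > budget:
            continue
        candidates = [
            a.GetIdx()
            for a in mol.GetAtoms()
            if a.GetIdx() < n_core and a.GetTotalNumHs() > 0 and a.GetSymbol() == "C"
        ]
        if not candidates:
            break
        atom = int(candidates[rng.integers(0, len(candidates))])
        attached = _attach(mol, SUBSTITUENTS[name], atom)
        if attached is not None:
            mol = attached
            budget -= frag_size
    return Chem.MolToSmiles(mol)


def synth_smiles(spec: SyntheticDatasetSpec) -> list[str]:
    """Exactly ``spec.n`` canonical, guaranteed-valid SMILES, deterministic in seed."""
    rng = np.random.default_rng(spec.seed)
    return [_one_molecule(spec, rng) for _ in range(spec.n)]


def toy_dataset(spec: SyntheticDatasetSpec) -> list[MoleculeRecord]:
    """Synthetic molecules as fully populated records (properties + scaffold)."""
    return [make_record(s) for s in synth_smiles(spec)]


def write_smi(smiles: list[str], path: str) -> None:
    with open(path, "w") as fh:
        for s in smiles:
            fh.write(s + "\n")
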