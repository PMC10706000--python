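"""Molecule parsing, property computation, scaffolds and graph conversion.

Molecules are carried as canonical SMILES.  Four conditioning properties are
computed per molecule — Crippen logP (lipophilicity), TPSA (topological polar
surface area, Å²), QED (drug-likeness in [0, 1]) and SAS (synthetic
accessibility, [1, 10], lower = easier) — together with the Bemis–Murcko
scaffold (ring systems plus linkers, side chains removed).

Graphs are heavy-atom graphs: nodes are non-hydrogen atoms carrying a
concatenation of four one-hot blocks (atom type, degree, hydrogen count,
implicit valence); edges are heavy-atom bonds.  Hydrogens are implicit — the
hydrogen-count block carries that information.
"""

from __future__ import annotations

import csv
import importlib.util
import logging
import os
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, QED, RDConfig
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import ConfigurationError, ParseError

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

PROPERTY_NAMES = ("logP", "TPSA", "QED", "SAS")

# Instrumentation: incremented on every molecular-graph construction.  The
# sampling path must never touch graphs (the graph encoder is a training-time
# device only), and tests assert this counter stays flat during generation.
GRAPH_BUILD_COUNT = 0


def _load_sascorer():
    path = os.path.join(RDConfig.RDContribDir, "SA_Score", "sascorer.py")
    spec = importlib.util.spec_from_file_location("sascorer", path)
    module = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(module)
    return module


_sascorer = _load_sascorer()


# --------------------------------------------------------------------- types
@dataclass(frozen=True)
class MoleculeRecord:
    """A canonical molecule with its conditioning properties and scaffold."""

    smiles: str
    properties: dict[str, float]
    scaffold: str


# One-hot vocabularies for node features.  Out-of-range values fall into the
# final ("other") bucket rather than raising: rare atoms must not crash
# featurization of large public sets.
ATOM_TYPES = ("C", "N", "O", "F", "S", "Cl", "Br", "I", "P", "B", "other")
DEGREE_CHOICES = tuple(range(6))
NUM_H_CHOICES = tuple(range(5))
VALENCE_CHOICES = tuple(range(6))
NODE_FEATURE_DIM = (
    len(ATOM_TYPES) + len(DEGREE_CHOICES) + len(NUM_H_CHOICES) + len(VALENCE_CHOICES)
)


@dataclass
class MolecularGraph:
    """Heavy-atom graph: one-hot node features plus undirected bond edges."""

    node_features: np.ndarray  # (N, NODE_FEATURE_DIM) float64, rows sum to 4
    edges: list[tuple[int, int]]  # unordered heavy-atom index pairs, no dups
    num_nodes: int

    def adjacency(self, self_loops: bool = True) -> np.ndarray:
        """Dense symmetric adjacency; self-loops included by default."""
        adj = np.zeros((self.num_nodes, self.num_nodes))
        for i, j in self.edges:
            adj[i, j] = adj[j, i] = 1.0
        if self_loops:
            np.fill_diagonal(adj, 1.0)
        return adj


# ---------------------------------------------------------------- operations
def _mol_from_smiles(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles:
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return RDKit's canonical SMILES; idempotent by construction."""
    return Chem.MolToSmiles(_mol_from_smiles(smiles))


def is_valid(smiles: str) -> bool:
    return bool(smiles) and Chem.MolFromSmiles(smiles) is not None


def compute_properties(smiles: str) -> dict[str, float]:
    """Compute the four conditioning properties {logP, TPSA, QED, SAS}."""
    mol = _mol_from_smiles(smiles)
    return {
        "logP": float(Crippen.MolLogP(mol)),
        "TPSA": float(Descriptors.TPSA(mol)),
        "QED": float(QED.qed(mol)),
        "SAS": float(_sascorer.calculateScore(mol)),
    }


def extract_scaffold(smiles: str) -> str:
    """Bemis–Murcko scaffold SMILES; empty string for acyclic molecules."""
    mol = _mol_from_smiles(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def _one_hot(value, choices) -> np.ndarray:
    vec = np.zeros(len(choices))
    try:
        idx = choices.index(value)
    except ValueError:
        idx = len(choices) - 1  # reserved "other"/overflow bucket
    vec[idx] = 1.0
    return vec


def mol_to_graph(smiles: str) -> MolecularGraph:
    """Convert a molecule to its heavy-atom graph with one-hot node features."""
    global GRAPH_BUILD_COUNT
    mol = _mol_from_smiles(smiles)
    GRAPH_BUILD_COUNT += 1
    features = []
    for atom in mol.GetAtoms():
        features.append(
            np.concatenate(
                [
                    _one_hot(atom.GetSymbol(), list(ATOM_TYPES)),
                    _one_hot(atom.GetDegree(), list(DEGREE_CHOICES)),
                    _one_hot(atom.GetTotalNumHs(), list(NUM_H_CHOICES)),
                    _one_hot(atom.GetImplicitValence(), list(VALENCE_CHOICES)),
                ]
            )
        )
    edges = []
    seen = set()
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        key = (min(i, j), max(i, j))
        if key not in seen:
            seen.add(key)
            edges.append(key)
    return MolecularGraph(
        node_features=np.asarray(features),
        edges=edges,
        num_nodes=mol.GetNumAtoms(),
    )


def make_record(smiles: str) -> MoleculeRecord:
    """Canonicalize and fully populate a MoleculeRecord."""
    canonical = canonicalize(smiles)
    return MoleculeRecord(
        smiles=canonical,
        properties=compute_properties(canonical),
        scaffold=extract_scaffold(canonical),
    )


def read_dataset(path: str, fmt: str | None = None) -> list[MoleculeRecord]:
    """Read a `.smi` (one SMILES per line) or CSV (``smiles`` column) dataset.

    Invalid lines are skipped with a logged count; precomputed property
    columns in CSVs are ignored in favor of recomputation so every record is
    internally consistent.
    """
    if not os.path.exists(path):
        raise ConfigurationError(f"dataset file not found: {path}")
    if fmt is None:
        fmt = "csv" if path.lower().endswith(".csv") else "smi"
    smiles_list: list[str] = []
    if fmt == "smi":
        with open(path) as fh:
            smiles_list = [line.strip().split()[0] for line in fh if line.strip()]
    elif fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "smiles" not in reader.fieldnames:
                raise ConfigurationError(f"CSV {path} lacks a 'smiles' column")
            smiles_list = [row["smiles"].strip() for row in reader if row["smiles"].strip()]
    else:
        raise ConfigurationError(f"unknown dataset format: {fmt}")

    records: list[MoleculeRecord] = []
    skipped = 0
    for smi in smiles_list:
        try:
            records.append(make_record(smi))
        except ParseError:
            skipped += 1
    if skipped:
        logger.warning("skipped %d invalid SMILES while reading %s", skipped, path)
    if not records:
        logger.warning("no valid molecules found in %s", path)
    return records


def write_dataset(records: list[MoleculeRecord], path: str) -> None:
    """Write records as CSV with all four properties and the scaffold."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["smiles", "logP", "TPSA", "QED", "SAS", "scaffold"])
        for rec in records:
            writer.writerow(
                [rec.smiles]
                + [f"{rec.properties[p]:.6g}" for p in PROPERTY_NAMES]
                + [rec.scaffold]
            )
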