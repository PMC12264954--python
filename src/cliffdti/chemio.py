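"""SMILES handling, ECFP fingerprints, and the three pairwise similarity criteria.

Activity-cliff mining declares two compounds "structurally similar" when at
least one of three criteria reaches a threshold (default 0.9):

* **substructure similarity** — Tanimoto over whole-molecule extended
  connectivity fingerprints (ECFP4: Morgan radius 2, 1024 bits by default);
* **scaffold similarity** — Tanimoto over ECFP of the Bemis-Murcko scaffolds;
* **SMILES similarity** — normalized Levenshtein similarity of the canonical
  SMILES strings, ``1 - d(a, b) / max(len(a), len(b))``.

All three are symmetric, lie in [0, 1], and equal 1 for a compound with
itself.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

#: Sentinel canonical "scaffold" for acyclic molecules (no ring system).
EMPTY_SCAFFOLD = ""

DEFAULT_RADIUS = 2
DEFAULT_N_BITS = 1024


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""

    def __init__(self, smiles: str):
        super().__init__(f"unparseable SMILES: {smiles!r}")
        self.smiles = smiles


@dataclass(frozen=True)
class SimilarityTriple:
    """Pairwise structural similarity under the three criteria."""

    substructure_sim: float
    scaffold_sim: float
    smiles_sim: float

    def max(self) -> float:
        return max(self.substructure_sim, self.scaffold_sim, self.smiles_sim)


@dataclass
class Molecule:
    """A featurized compound: id, canonical SMILES, and ECFP bit vector."""

    compound_id: str
    smiles: str
    fingerprint: np.ndarray = field(repr=False)
    scaffold: str = EMPTY_SCAFFOLD
    scaffold_fingerprint: np.ndarray | None = field(default=None, repr=False)
    radius: int = DEFAULT_RADIUS
    n_bits: int = DEFAULT_N_BITS


def _parse(smiles: str) -> Chem.Mol:
    if not isinstance(smiles, str) or not smiles:
        raise SmilesParseError(str(smiles))
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def canonicalize_smiles(smiles: str) -> str:
    """Return the canonical SMILES; identical molecules map to the same string."""
    return Chem.MolToSmiles(_parse(smiles))


def compute_ecfp(smiles: str, radius: int = DEFAULT_RADIUS,
                 n_bits: int = DEFAULT_N_BITS) -> np.ndarray:
    """Extended-connectivity (Morgan) fingerprint as a uint8 0/1 vector."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 8:
        raise ValueError("n_bits must be >= 8")
    mol = _parse(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    for bit in gen.GetFingerprint(mol).GetOnBits():
        arr[bit] = 1
    return arr


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity |a AND b| / |a OR b| of two bit vectors.

    Two all-zero vectors have no defined Tanimoto; by convention 0 is
    returned with a warning.
    """
    fp_a = np.asarray(fp_a)
    fp_b = np.asarray(fp_b)
    if fp_a.shape != fp_b.shape:
        raise ValueError(f"fingerprint length mismatch: {fp_a.shape} vs {fp_b.shape}")
    a = fp_a.astype(bool)
    b = fp_b.astype(bool)
    union = int(np.count_nonzero(a | b))
    if union == 0:
        warnings.warn("Tanimoto of two empty fingerprints is undefined; returning 0")
        return 0.0
    return int(np.count_nonzero(a & b)) / union


def scaffold_of(smiles: str) -> str:
    """Canonical SMILES of the Bemis-Murcko scaffold (ring systems + linkers).

    Acyclic molecules have no ring system; the empty-string sentinel
    :data:`EMPTY_SCAFFOLD` is returned for them.
    """
    mol = _parse(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return EMPTY_SCAFFOLD
    return Chem.MolToSmiles(scaffold)


def smiles_similarity(s_a: str, s_b: str) -> float:
    """Normalized Levenshtein similarity of two (canonical) SMILES strings."""
    if not s_a or not s_b:
        raise ValueError("smiles_similarity requires non-empty strings")
    dist = edlib.align(s_a, s_b, task="distance", mode="NW")["editDistance"]
    return 1.0 - dist / max(len(s_a), len(s_b))


def featurize(compound_id: str, smiles: str, radius: int = DEFAULT_RADIUS,
              n_bits: int = DEFAULT_N_BITS) -> Molecule:
    """Canonicalize and fingerprint one compound, including its scaffold."""
    canon = canonicalize_smiles(smiles)
    fp = compute_ecfp(canon, radius=radius, n_bits=n_bits)
    scaf = scaffold_of(canon)
    scaf_fp = None
    if scaf != EMPTY_SCAFFOLD:
        scaf_fp = compute_ecfp(scaf, radius=radius, n_bits=n_bits)
    return Molecule(compound_id=compound_id, smiles=canon, fingerprint=fp,
                    scaffold=scaf, scaffold_fingerprint=scaf_fp,
                    radius=radius, n_bits=n_bits)


def similarity_triple(mol_a: Molecule, mol_b: Molecule) -> SimilarityTriple:
    """Compute the three-way similarity of two featurized molecules.

    Scaffold convention: if exactly one scaffold is empty the scaffold
    similarity is 0; if both are empty (two acyclic molecules) it is 1.
    """
    sub = tanimoto(mol_a.fingerprint, mol_b.fingerprint)
    a_empty = mol_a.scaffold == EMPTY_SCAFFOLD
    b_empty = mol_b.scaffold == EMPTY_SCAFFOLD
    if a_empty and b_empty:
        scaf = 1.0
    elif a_empty or b_empty:
        scaf = 0.0
    else:
        scaf = tanimoto(mol_a.scaffold_fingerprint, mol_b.scaffold_fingerprint)
    smi = smiles_similarity(mol_a.smiles, mol_b.smiles)
    return SimilarityTriple(substructure_sim=sub, scaffold_sim=scaf, smiles_sim=smi)


def write_featurization_metadata(path: str | Path, radius: int, n_bits: int) -> None:
    """Record fingerprint settings and toolkit version next to cached features."""
    import rdkit

    meta = {"radius": radius, "n_bits": n_bits, "toolkit": f"rdkit {rdkit.__version__}"}
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")
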