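"""ECFP4 featurization: canonical SMILES -> folded binary fingerprints.

Extended-connectivity fingerprints of radius 2 (ECFP4) hashed into a fixed
number of bits (default 2048) are the model input.  Hydrogens are implicit;
fold collisions are accepted silently, as is standard practice.
"""

from __future__ import annotations

import numpy as np

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .curation import LabelMatrix, SmilesParseError

DEFAULT_N_BITS = 2048
_generators: dict[int, object] = {}


def _generator(n_bits: int):
    if n_bits not in _generators:
        _generators[n_bits] = rdFingerprintGenerator.GetMorganGenerator(
            radius=2, fpSize=n_bits
        )
    return _generators[n_bits]


def ecfp4(smiles: str, n_bits: int = DEFAULT_N_BITS) -> np.ndarray:
    """Folded radius-2 circular fingerprint as a uint8 0/1 vector.

    Deterministic, and invariant to rewriting the SMILES of the same
    molecule (the hash is computed on the molecular graph).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return _generator(n_bits).GetFingerprintAsNumPy(mol).astype(np.uint8)


def n_environments(smiles: str) -> int:
    """Number of distinct atom environments at radii 0-2 (pre-folding).

    Upper bound for the popcount of the folded fingerprint; the difference
    counts fold collisions.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    sparse_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2)
    return len(sparse_gen.GetSparseCountFingerprint(mol).GetNonzeroElements())


def featurize_matrix(
    matrix: LabelMatrix, n_bits: int = DEFAULT_N_BITS
) -> tuple[np.ndarray, LabelMatrix]:
    """Fingerprint every compound of a label matrix, rows aligned.

    Returns (fingerprints, matrix) where fingerprints has shape
    (n_compounds, n_bits) and row i matches compound i. Any unparsable
    compound aborts with the offending structure listed (curated matrices
    never trigger this).
    """
    fps = np.zeros((matrix.n_compounds, n_bits), dtype=np.uint8)
    bad = []
    for i, smi in enumerate(matrix.smiles):
        try:
            fps[i] = ecfp4(smi, n_bits=n_bits)
        except SmilesParseError:
            bad.append(smi)
    if bad:
        raise SmilesParseError("; ".join(bad))
    return fps, matrix
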