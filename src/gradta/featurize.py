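"""Featurization of drugs (SMILES -> molecular graph) and proteins (sequence -> integer encoding).

Drugs are represented as 2D molecular graphs: atoms are nodes carrying a
78-dimensional binary feature vector, bonds are undirected edges stored as
both directed arcs.  Proteins are represented as fixed-length integer
sequences over a 25-letter amino-acid alphabet, zero-padded (or truncated)
to 1000 positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

# 44-symbol atom vocabulary (43 named elements + trailing "unknown" slot),
# the DeepChem-derived list conventional in molecular-graph DTA models.
ATOM_VOCAB: tuple[str, ...] = (
    "C", "N", "O", "S", "F", "Si", "P", "Cl", "Br", "Mg", "Na", "Ca", "Fe",
    "As", "Al", "I", "B", "V", "K", "Tl", "Yb", "Sb", "Sn", "Ag", "Pd", "Co",
    "Se", "Ti", "Zn", "H", "Li", "Ge", "Cu", "Au", "Ni", "Cd", "In", "Mn",
    "Zr", "Cr", "Pt", "Hg", "Pb", "Unknown",
)

# 25-letter amino-acid alphabet (20 standard residues plus the extended
# codes B, O, U, X, Z); index 0 is reserved exclusively for padding,
# residues map to 1..25.
PROTEIN_ALPHABET: str = "ABCDEFGHIKLMNOPQRSTUVWXYZ"
PROTEIN_INDEX: dict[str, int] = {c: i + 1 for i, c in enumerate(PROTEIN_ALPHABET)}

ATOM_FEATURE_DIM = 78       # 44 + 11 + 11 + 11 + 1
PROTEIN_ENCODED_LENGTH = 1000

# one-hot block offsets within the 78-dim atom feature vector
_SYMBOL_OFFSET = 0
_DEGREE_OFFSET = 44
_NUM_H_OFFSET = 55
_VALENCE_OFFSET = 66
_AROMATIC_BIT = 77
_CATEGORY_BINS = 11         # degree / H-count / valence each cover 0..10


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class ProteinEncodingError(ValueError):
    """Raised when a sequence contains a character outside the alphabet."""


@dataclass(frozen=True)
class MolecularGraph:
    """Drug molecule as a node-feature matrix plus a directed edge index.

    ``node_features`` is an ``(n_atoms, 78)`` binary matrix; ``edge_index``
    is a ``(2, 2 * n_bonds)`` integer matrix holding both directions of
    every bond so that mean aggregation sees the incoming neighbourhood of
    each atom of the undirected molecule.
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    n_atoms: int
    n_bonds: int

    def neighbors(self, v: int) -> np.ndarray:
        """Atom indices adjacent to atom ``v``."""
        src, dst = self.edge_index
        return src[dst == v]


@dataclass(frozen=True)
class ProteinEncoding:
    """Protein sequence as a fixed-length (1000) integer vector.

    Residues map to 1..25; trailing zeros are padding.  ``original_length``
    is the length of the sequence before truncation/padding.
    """

    indices: np.ndarray
    original_length: int

    @property
    def effective_length(self) -> int:
        return min(self.original_length, PROTEIN_ENCODED_LENGTH)


def atom_feature_vector(
    symbol: str,
    degree: int,
    num_h: int,
    valence: int,
    aromatic: bool,
) -> np.ndarray:
    """Encode one atom as the 78-dim binary feature vector.

    Four one-hot blocks (element symbol, degree, attached hydrogens,
    implicit valence) plus a single aromaticity bit.  Unknown element
    symbols fall into the vocabulary's final slot; degree/H/valence values
    above 10 clip into the last bin so featurization is total.
    """
    if min(degree, num_h, valence) < 0:
        raise ValueError("degree, num_h and valence must be non-negative")
    vec = np.zeros(ATOM_FEATURE_DIM, dtype=np.float64)
    try:
        sym_idx = ATOM_VOCAB.index(symbol)
    except ValueError:
        sym_idx = len(ATOM_VOCAB) - 1
    vec[_SYMBOL_OFFSET + sym_idx] = 1.0
    vec[_DEGREE_OFFSET + min(degree, _CATEGORY_BINS - 1)] = 1.0
    vec[_NUM_H_OFFSET + min(num_h, _CATEGORY_BINS - 1)] = 1.0
    vec[_VALENCE_OFFSET + min(valence, _CATEGORY_BINS - 1)] = 1.0
    vec[_AROMATIC_BIT] = 1.0 if aromatic else 0.0
    return vec


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Node order follows the parser's atom order; both directions of every
    bond are stored.  Raises :class:`SmilesParseError` on invalid input.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    feats = np.zeros((mol.GetNumAtoms(), ATOM_FEATURE_DIM), dtype=np.float64)
    for atom in mol.GetAtoms():
        feats[atom.GetIdx()] = atom_feature_vector(
            atom.GetSymbol(),
            atom.GetDegree(),
            atom.GetTotalNumHs(),
            atom.GetImplicitValence(),
            atom.GetIsAromatic(),
        )
    edges: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((u, v))
        edges.append((v, u))
    edge_index = (
        np.array(edges, dtype=np.int64).T
        if edges
        else np.zeros((2, 0), dtype=np.int64)
    )
    return MolecularGraph(
        node_features=feats,
        edge_index=edge_index,
        n_atoms=mol.GetNumAtoms(),
        n_bonds=mol.GetNumBonds(),
    )


def aromatic_atom_count(smiles: str) -> int:
    """Number of aromatic atoms in the molecule (used by the synthetic signal)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    return sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())


def encode_protein(sequence: str) -> ProteinEncoding:
    """Encode an amino-acid sequence as a length-1000 integer vector.

    Residues map through :data:`PROTEIN_INDEX`; sequences longer than 1000
    keep their first 1000 residues, shorter ones are padded with 0.
    """
    seq = sequence.upper()
    indices = np.zeros(PROTEIN_ENCODED_LENGTH, dtype=np.int64)
    for pos, ch in enumerate(seq[:PROTEIN_ENCODED_LENGTH]):
        idx = PROTEIN_INDEX.get(ch)
        if idx is None:
            raise ProteinEncodingError(
                f"character {ch!r} at position {pos} is not in the "
                f"25-letter amino-acid alphabet"
            )
        indices[pos] = idx
    # validate the truncated tail too, so errors do not depend on length
    for pos, ch in enumerate(seq[PROTEIN_ENCODED_LENGTH:], PROTEIN_ENCODED_LENGTH):
        if ch not in PROTEIN_INDEX:
            raise ProteinEncodingError(
                f"character {ch!r} at position {pos} is not in the "
                f"25-letter amino-acid alphabet"
            )
    return ProteinEncoding(indices=indices, original_length=len(seq))


def decode_protein(enc: ProteinEncoding) -> str:
    """Inverse of :func:`encode_protein` up to truncation (drops padding)."""
    chars = [PROTEIN_ALPHABET[i - 1] for i in enc.indices[: enc.effective_length]]
    return "".join(chars)


def read_smiles_file(path) -> list[str]:
    """Read SMILES one-per-line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                out.append(line.split()[0])
    return out


def read_fasta(path) -> dict[str, str]:
    """Read a multi-record FASTA file into an id -> sequence mapping."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: dict[str, str]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(s), id=k, description="") for k, s in records.items()],
        str(path),
        "fasta",
    )
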