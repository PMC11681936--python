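"""Structure parsing and residue contact-map construction.

A chain is reduced to one representative atom per residue (C-alpha by
default).  From the ordered coordinates we compute the Euclidean
residue-residue distance matrix, threshold it into a binary contact map, and
normalize the resulting adjacency with self-loops,

    A_norm = D^{-1/2} (A + I) D^{-1/2},

where D is the degree matrix of A + I.  The normalized operator is what the
graph convolution consumes.  A consistency filter drops chains whose parsed
residue count disagrees with the row count of their sequence embedding
(e.g. residues missing the representative atom in the structure file), since
such chains cannot align node features to graph vertices.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Data.PDBData import protein_letters_3to1
from Bio.PDB import PDBParser
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "ResidueChain",
    "ContactGraph",
    "parse_chain",
    "read_fasta",
    "distance_matrix",
    "build_contact_map",
    "normalize_adjacency",
    "check_consistency",
    "write_contact_tsv",
    "write_edge_list",
]


@dataclass
class ResidueChain:
    """One chain: ordered one-letter sequence plus representative-atom coords."""

    chain_id: str
    sequence: str
    coords: np.ndarray  # (L, 3) float, Angstrom

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.sequence) != self.coords.shape[0]:
            raise ValueError(
                f"sequence length {len(self.sequence)} != coordinate rows "
                f"{self.coords.shape[0]}"
            )
        if len(self.sequence) < 1:
            raise ValueError("chain must contain at least one residue")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ContactGraph:
    """Binary contact adjacency, its normalized form, and node features."""

    adjacency: np.ndarray     # (L, L) binary, zero diagonal
    normalized: np.ndarray    # (L, L) real symmetric
    node_features: np.ndarray  # (L, d)

    def __post_init__(self):
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency entries must be 0/1")
        if np.abs(self.normalized - self.normalized.T).max() > 1e-9:
            raise ValueError("normalized adjacency must be symmetric")
        if self.node_features.shape[0] != a.shape[0]:
            raise ValueError("node_features row count must equal L")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def parse_chain(
    structure_text: str,
    chain_id: str,
    representative_atom: str = "CA",
) -> ResidueChain:
    """Parse one chain from PDB-format text (first model only).

    Residues lacking the representative atom are skipped with a warning; the
    resulting length shrink is what the downstream consistency filter
    detects.  HETATM residues (waters, ligands) are ignored.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("chain", io.StringIO(structure_text))
    model = next(structure.get_models())
    chain_ids = [c.id for c in model]
    if chain_id not in chain_ids:
        raise KeyError(f"chain {chain_id!r} not found; present: {chain_ids}")
    chain = model[chain_id]
    seq: list[str] = []
    coords: list[np.ndarray] = []
    for residue in chain:
        if residue.id[0] != " ":  # skip HETATM / water
            continue
        resname = residue.get_resname()
        letter = protein_letters_3to1.get(resname, "X")
        if representative_atom not in residue:
            warnings.warn(
                f"residue {resname} {residue.id[1]} in chain {chain_id} lacks "
                f"atom {representative_atom}; skipped"
            )
            continue
        seq.append(letter)
        coords.append(residue[representative_atom].get_coord())
    if not coords:
        raise ValueError(
            f"chain {chain_id!r} has no residue with atom {representative_atom}"
        )
    return ResidueChain(chain_id, "".join(seq), np.asarray(coords, dtype=float))


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an {id: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def distance_matrix(chain: ResidueChain) -> np.ndarray:
    """Pairwise Euclidean distances between representative atoms (Angstrom)."""
    if len(chain) == 1:
        return np.zeros((1, 1))
    return squareform(pdist(chain.coords))


def build_contact_map(dist: np.ndarray, threshold: float) -> np.ndarray:
    """Binary contact map: 1 iff 0 < d(i,j) <= threshold, zero diagonal.

    Self-loops are *not* stored here; they enter only in
    :func:`normalize_adjacency`.
    """
    if threshold <= 0:
        raise ValueError(f"contact threshold must be positive, got {threshold}")
    dist = np.asarray(dist, dtype=float)
    adj = ((dist > 0) & (dist <= threshold)).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj


def normalize_adjacency(adjacency: np.ndarray) -> np.ndarray:
    """Self-looped symmetric normalization D^{-1/2} (A + I) D^{-1/2}."""
    a = np.asarray(adjacency, dtype=float)
    a_hat = a + np.eye(a.shape[0])
    deg = a_hat.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)  # self-loop guarantees deg >= 1
    return a_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def check_consistency(chain: ResidueChain, embedding) -> bool:
    """True iff the chain length matches the embedding row count.

    Pairs where either member fails this check are dropped by the pipeline:
    their graph vertices cannot be matched to per-residue feature rows.
    """
    values = getattr(embedding, "values", embedding)
    return len(chain) == np.asarray(values).shape[0]


def write_contact_tsv(
    path: str | Path,
    adjacency: np.ndarray,
    threshold: float,
    atom: str = "CA",
) -> None:
    """Dense contact map as TSV with a one-line provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# contact_map threshold={threshold} atom={atom}\n")
        for row in np.asarray(adjacency, dtype=int):
            fh.write("\t".join(str(v) for v in row) + "\n")


def write_edge_list(
    path: str | Path,
    dist: np.ndarray,
    threshold: float,
    atom: str = "CA",
) -> None:
    """Sparse upper-triangle contact list: 1-based i, j, and distance."""
    adj = build_contact_map(dist, threshold)
    with open(path, "w") as fh:
        fh.write(f"# edges threshold={threshold} atom={atom}\n")
        fh.write("i\tj\tdistance\n")
        ii, jj = np.nonzero(np.triu(adj, 1))
        for i, j in zip(ii, jj):
            fh.write(f"{i + 1}\t{j + 1}\t{dist[i, j]:.3f}\n")
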