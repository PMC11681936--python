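"""Synthetic data generators: toy structures and planted-signal pair sets.

These generators make the whole pipeline testable without downloads or a
GPU.  They validate mechanics, not biology:

* :func:`make_toy_pdb` writes single-chain PDB text with one C-alpha per
  residue at the physical consecutive spacing of 3.8 Angstrom, in extended,
  ideal-helix, or self-avoiding random-walk geometry.  An ideal helix at a
  10 Angstrom cutoff is in contact out to |i-j| of about 6 (a dense band of
  mutual contacts), an extended chain only to |i-j| <= 2 — which makes
  backbone geometry a clean graph-only class signal.
* :func:`make_planted_dataset` builds a balanced labelled pair set whose
  interaction rule is known and recoverable.  Under the ``embedding`` rule a
  pair interacts iff *both* members carry a planted motif: a dedicated
  high-magnitude embedding channel over a random 3-residue window.  Under
  the ``structure`` rule a pair interacts iff both members have helical
  (contact-dense) geometry; embeddings then carry no class information.
  Negatives are random receptor-peptide pairings drawn outside the
  interacting grid, so labels follow the planted rule exactly.

Everything is deterministic under a fixed seed; regenerating produces
byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.Data.IUPACData import protein_letters_1to3

from .embeddings import EmbeddingMatrix, SyntheticEmbedder
from .structures_io import ResidueChain, parse_chain
from .train_eval import PairDataset, SamplePair, write_pairs_tsv

__all__ = [
    "FixtureSpec",
    "make_toy_pdb",
    "make_chain",
    "make_planted_dataset",
    "corrupt_pdb",
    "write_dataset",
]

# ideal alpha-helix C-alpha parameters: radius (A), rise per residue (A),
# turn per residue (degrees); consecutive C-alpha spacing ~3.8 A
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TURN_DEG = 100.0
_CA_SPACING = 3.8


@dataclass
class FixtureSpec:
    """Parameters of a planted-signal interaction dataset."""

    n_receptors: int = 20
    n_peptides: int = 20
    n_pairs: int = 200
    receptor_length_range: tuple[int, int] = (25, 40)
    peptide_length_range: tuple[int, int] = (8, 15)
    planted_rule: str = "embedding"  # embedding | structure
    embedding_dim: int = 16
    motif_channel: int = 0
    motif_magnitude: float = 5.0
    motif_width: int = 3
    seed: int = 0

    def __post_init__(self):
        for lo, hi in (self.receptor_length_range, self.peptide_length_range):
            if lo < 1 or hi < lo:
                raise ValueError("length ranges must be nonempty")
        if self.planted_rule not in ("embedding", "structure"):
            raise ValueError("planted_rule must be 'embedding' or 'structure'")


def _coords(sequence: str, geometry: str, rng: np.random.Generator
            ) -> np.ndarray:
    n = len(sequence)
    if geometry == "extended":
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * _CA_SPACING
        return coords
    if geometry == "helix":
        t = np.arange(n) * np.deg2rad(_HELIX_TURN_DEG)
        return np.column_stack([
            _HELIX_RADIUS * np.cos(t),
            _HELIX_RADIUS * np.sin(t),
            np.arange(n) * _HELIX_RISE,
        ])
    if geometry == "random_walk":
        coords = np.zeros((n, 3))
        for i in range(1, n):
            # rejection-sample a step that keeps >2 A from earlier residues
            for _ in range(200):
                step = rng.standard_normal(3)
                step *= _CA_SPACING / np.linalg.norm(step)
                cand = coords[i - 1] + step
                if i < 2 or np.min(
                    np.linalg.norm(coords[: i - 1] - cand, axis=1)
                ) > 2.0:
                    break
            coords[i] = cand
        return coords
    raise ValueError(f"unknown geometry {geometry!r}")


def make_toy_pdb(sequence: str, geometry: str = "extended",
                 seed: int = 0, chain_id: str = "A") -> str:
    """PDB text with one CA ATOM record per residue; parseable round-trip."""
    if not sequence:
        raise ValueError("sequence must be nonempty")
    for ch in sequence:
        if ch != "X" and ch.upper() not in protein_letters_1to3:
            raise ValueError(f"invalid residue letter {ch!r}")
    rng = np.random.default_rng(np.random.PCG64(seed))
    coords = _coords(sequence, geometry, rng)
    lines = []
    for i, (ch, (x, y, z)) in enumerate(zip(sequence, coords), start=1):
        res3 = "UNK" if ch == "X" else protein_letters_1to3[ch.upper()].upper()
        lines.append(
            f"ATOM  {i:5d}  CA  {res3:>3s} {chain_id}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_chain(sequence: str, geometry: str = "extended", seed: int = 0,
               chain_id: str = "A") -> ResidueChain:
    """Build the chain by writing and re-parsing toy PDB text."""
    return parse_chain(make_toy_pdb(sequence, geometry, seed, chain_id),
                       chain_id)


def corrupt_pdb(pdb_text: str, drop_residue: int = 1) -> str:
    """Remove one residue's ATOM record (1-based) to force a length mismatch."""
    out = []
    for line in pdb_text.splitlines():
        if line.startswith("ATOM") and int(line[22:26]) == drop_residue:
            continue
        out.append(line)
    return "\n".join(out) + "\n"


_LETTERS = "ACDEFGHIKLMNPQRSTVWY"


def _random_sequence(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(_LETTERS[i] for i in rng.integers(0, len(_LETTERS), n))


def _plant_motif(emb: np.ndarray, spec: FixtureSpec,
                 rng: np.random.Generator) -> np.ndarray:
    out = emb.copy()
    width = min(spec.motif_width, out.shape[0])
    start = int(rng.integers(0, out.shape[0] - width + 1))
    out[start : start + width, spec.motif_channel] += spec.motif_magnitude
    return out


def make_planted_dataset(spec: FixtureSpec) -> PairDataset:
    """Generate chains, embeddings and a balanced labelled pair list."""
    rng = np.random.default_rng(np.random.PCG64(spec.seed))
    embedder = SyntheticEmbedder(dim=spec.embedding_dim, seed=spec.seed)

    chains: dict[str, ResidueChain] = {}
    embeddings: dict[str, EmbeddingMatrix] = {}
    carriers: dict[str, bool] = {}

    def build(prefix: str, count: int, length_range: tuple[int, int]) -> list[str]:
        ids = []
        for i in range(count):
            cid = f"{prefix}{i:03d}"
            seq = _random_sequence(rng, *length_range)
            carrier = i < (count + 1) // 2
            if spec.planted_rule == "structure":
                geometry = "helix" if carrier else "extended"
            else:
                geometry = "random_walk"
            chains[cid] = make_chain(seq, geometry,
                                     seed=int(rng.integers(0, 2**31)))
            emb = embedder.embed(seq).values
            if spec.planted_rule == "embedding" and carrier:
                emb = _plant_motif(emb, spec, rng)
            embeddings[cid] = EmbeddingMatrix(emb, source=embedder.name)
            carriers[cid] = carrier
            ids.append(cid)
        return ids

    receptor_ids = build("R", spec.n_receptors, spec.receptor_length_range)
    peptide_ids = build("P", spec.n_peptides, spec.peptide_length_range)

    pos_grid = [(r, p) for r in receptor_ids for p in peptide_ids
                if carriers[r] and carriers[p]]
    neg_grid = [(r, p) for r in receptor_ids for p in peptide_ids
                if not (carriers[r] and carriers[p])]
    n_pos = spec.n_pairs // 2
    n_neg = spec.n_pairs - n_pos
    if n_pos > len(pos_grid) or n_neg > len(neg_grid):
        raise ValueError(
            f"infeasible counts: need {n_pos} interacting and {n_neg} "
            f"non-interacting pairs but grids hold {len(pos_grid)} and "
            f"{len(neg_grid)}"
        )
    pos_idx = rng.choice(len(pos_grid), size=n_pos, replace=False)
    neg_idx = rng.choice(len(neg_grid), size=n_neg, replace=False)
    pairs = [SamplePair(*pos_grid[i], 1) for i in pos_idx]
    pairs += [SamplePair(*neg_grid[i], 0) for i in neg_idx]
    order = rng.permutation(len(pairs))
    return PairDataset([pairs[i] for i in order], chains, embeddings)


def write_dataset(directory: str | Path, dataset: PairDataset,
                  corrupt_id: str | None = None) -> dict[str, Path]:
    """Write PDBs, a FASTA of original sequences, and the pair-list TSV.

    If `corrupt_id` names a chain, its PDB loses residue 1 while the FASTA
    keeps the full sequence — the mismatch the consistency filter must
    catch.  Embeddings are exported as one .npy per chain (they carry the
    planted motif, which is not derivable from the FASTA).  Returns the
    paths written.
    """
    directory = Path(directory)
    structures = directory / "structures"
    structures.mkdir(parents=True, exist_ok=True)
    emb_dir = directory / "embeddings"
    emb_dir.mkdir(parents=True, exist_ok=True)
    fasta = directory / "sequences.fasta"
    with open(fasta, "w") as fh:
        for cid, chain in sorted(dataset.chains.items()):
            fh.write(f">{cid}\n{chain.sequence}\n")
            pdb_text = _pdb_from_chain(chain)
            if cid == corrupt_id:
                pdb_text = corrupt_pdb(pdb_text)
            (structures / f"{cid}.pdb").write_text(pdb_text)
            np.save(emb_dir / f"{cid}.npy", dataset.embeddings[cid].values)
    pairs_path = directory / "pairs.tsv"
    write_pairs_tsv(pairs_path, dataset.pairs)
    return {"structures": structures, "fasta": fasta, "pairs": pairs_path,
            "embeddings": emb_dir}


def _pdb_from_chain(chain: ResidueChain) -> str:
    lines = []
    for i, (ch, (x, y, z)) in enumerate(
        zip(chain.sequence, chain.coords), start=1
    ):
        res3 = "UNK" if ch == "X" else protein_letters_1to3[ch.upper()].upper()
        lines.append(
            f"ATOM  {i:5d}  CA  {res3:>3s} {chain.chain_id}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
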