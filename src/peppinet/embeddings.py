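"""Per-residue embeddings behind a pluggable provider interface.

The model consumes an L x d matrix of per-residue feature vectors (d = 1024
for a full-scale protein language model).  Providers implement a single
``embed(sequence)`` method.  The bundled :class:`SyntheticEmbedder` is fully
deterministic given its seed and needs no download: each amino-acid letter
gets a seeded base vector, a seeded positional perturbation is added so that
repeated letters still produce distinct rows, and rows are unit-normalized.
A real pretrained language model can be wrapped behind the same interface;
nothing in this package requires one.

Fixed-length zero padding (default L_max = 1200) prepares the matrix for the
convolutional sequence branch.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EmbeddingMatrix",
    "PaddedEmbedding",
    "SyntheticEmbedder",
    "EmbeddingCache",
    "embed",
    "pad",
    "VALID_LETTERS",
]

VALID_LETTERS = "ACDEFGHIKLMNPQRSTVWYX"


@dataclass
class EmbeddingMatrix:
    """L x d per-residue embedding with a provider tag."""

    values: np.ndarray
    source: str = "unknown"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("embedding must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding entries must be finite")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]


@dataclass
class PaddedEmbedding:
    """Fixed-length embedding: first `true_length` rows real, rest zero."""

    values: np.ndarray
    true_length: int

    def __post_init__(self):
        if self.true_length > self.values.shape[0]:
            raise ValueError("true_length exceeds padded length")
        if np.any(self.values[self.true_length:] != 0):
            raise ValueError("rows beyond true_length must be zero")


class SyntheticEmbedder:
    """Deterministic stand-in embedder: letter identity + position signal.

    Row i for letter a is unit_normalize(base[a] + 0.3 * pos[i]) where base
    and pos are seeded standard-normal draws.  Distinct seeds give distinct
    matrices; a fixed seed fixes the matrix exactly.
    """

    def __init__(self, dim: int = 1024, seed: int = 0):
        if dim < 1:
            raise ValueError("embedding dimension must be >= 1")
        self.dim = dim
        self.seed = seed
        rng = np.random.default_rng(np.random.PCG64(seed))
        self._base = {
            letter: rng.standard_normal(dim) for letter in VALID_LETTERS
        }
        self._pos_rng_seed = seed + 1

    @property
    def name(self) -> str:
        return f"synthetic(d={self.dim},seed={self.seed})"

    def embed(self, sequence: str) -> EmbeddingMatrix:
        for i, ch in enumerate(sequence):
            if ch not in self._base:
                raise ValueError(
                    f"unknown residue letter {ch!r} at position {i + 1}"
                )
        pos_rng = np.random.default_rng(np.random.PCG64(self._pos_rng_seed))
        pos = pos_rng.standard_normal((len(sequence), self.dim))
        rows = np.stack([self._base[ch] for ch in sequence]) + 0.3 * pos
        rows /= np.linalg.norm(rows, axis=1, keepdims=True)
        return EmbeddingMatrix(rows, source=self.name)


def embed(sequence: str, provider) -> EmbeddingMatrix:
    """Embed a sequence with any provider exposing .embed(sequence)."""
    return provider.embed(sequence)


def pad(embedding: EmbeddingMatrix, l_max: int = 1200) -> PaddedEmbedding:
    """Zero-pad (or head-truncate, with a warning) to exactly l_max rows."""
    values = embedding.values
    length = values.shape[0]
    if length > l_max:
        warnings.warn(
            f"sequence length {length} exceeds maximum {l_max}; "
            f"keeping the N-terminal {l_max} residues"
        )
        return PaddedEmbedding(values[:l_max].copy(), l_max)
    out = np.zeros((l_max, values.shape[1]))
    out[:length] = values
    return PaddedEmbedding(out, length)


class EmbeddingCache:
    """On-disk cache keyed by (provider tag, sequence hash).

    Arrays are stored as .npy with a JSON sidecar recording the provider and
    the sequence digest, so a cache hit can be trusted across runs.
    """

    def __init__(self, directory: str | Path):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    def _key(self, provider_name: str, sequence: str) -> str:
        digest = hashlib.sha256(
            f"{provider_name}\n{sequence}".encode()
        ).hexdigest()[:24]
        return digest

    def get_or_compute(self, provider, sequence: str) -> EmbeddingMatrix:
        key = self._key(provider.name, sequence)
        npy = self.directory / f"{key}.npy"
        meta = self.directory / f"{key}.json"
        if npy.exists() and meta.exists():
            values = np.load(npy)
            with open(meta) as fh:
                source = json.load(fh)["provider"]
            return EmbeddingMatrix(values, source=source)
        emb = provider.embed(sequence)
        np.save(npy, emb.values)
        with open(meta, "w") as fh:
            json.dump(
                {"provider": provider.name, "length": emb.length, "dim": emb.dim},
                fh,
            )
        return emb
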