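"""End-to-end peptide-protein interaction model.

Both chains of a pair pass through shared (siamese) encoders: the
convolutional sequence branch over the padded per-residue embedding and the
topology-adaptive graph branch over the contact graph.  Each branch emits a
fixed-size feature vector; the two are blended per chain with the fusion
weight, concatenated across the pair, and classified by the BN-ReLU head.

The per-chain *encodings* (padded embedding and the stacked adjacency-power
features [X, AX, ..., A^K X]) are constants during training, so they are
precomputed once by :meth:`PepPIModel.encode_chain`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .config import RunConfig
from .embeddings import VALID_LETTERS, EmbeddingMatrix, pad
from .fusion_head import PredictionHead, Prediction
from .graph_encoder import GraphEncoder, adjacency_power_features
from .seq_encoder import TextCNN
from .structures_io import (
    ResidueChain,
    build_contact_map,
    distance_matrix,
    normalize_adjacency,
)

__all__ = ["ChainEncoding", "PepPIModel"]

_AA_INDEX = {ch: i for i, ch in enumerate(VALID_LETTERS)}


def _onehot(sequence: str) -> np.ndarray:
    out = np.zeros((len(sequence), len(VALID_LETTERS)))
    for i, ch in enumerate(sequence):
        out[i, _AA_INDEX.get(ch, _AA_INDEX["X"])] = 1.0
    return out


@dataclass
class ChainEncoding:
    """Precomputed constant inputs for one chain."""

    chain_id: str
    padded: np.ndarray          # (L_max, d)
    power_features: np.ndarray  # (L, (K+1)*C_node)
    true_length: int


class PepPIModel:
    """Siamese two-branch interaction classifier."""

    def __init__(self, config: RunConfig):
        config.validate()
        if config.conv_channels != config.feature_dim:
            raise ValueError(
                "conv_channels must equal feature_dim: the sequence branch's "
                "global max-pool emits one value per conv channel"
            )
        self.config = config
        rng = np.random.default_rng(np.random.PCG64(config.seed))
        if config.node_feature_source == "embedding":
            node_dim = config.embedding_dim
        elif config.node_feature_source == "onehot":
            node_dim = len(VALID_LETTERS)
        else:  # degree: featureless graph, topology only
            node_dim = 1
        self.node_dim = node_dim
        self.seq_encoder = TextCNN(
            config.embedding_dim, config.conv_channels, rng,
            kernel=config.kernel_size, pool=config.pool_size,
        )
        self.graph_encoder = GraphEncoder(
            node_dim, config.tag_channels, config.feature_dim,
            config.tag_k, rng,
        )
        self.head = PredictionHead(2 * config.feature_dim,
                                   tuple(config.head_widths), rng)

    # --------------------------------------------------------------- params

    def parameters(self) -> list[Tensor]:
        return (self.seq_encoder.parameters()
                + self.graph_encoder.parameters()
                + self.head.parameters())

    def named_arrays(self) -> dict[str, np.ndarray]:
        arrays = {}
        for i, p in enumerate(self.parameters()):
            arrays[f"param_{i}"] = p.data
        for j, bn in enumerate(self.head.norms):
            arrays[f"bn_{j}_mean"] = bn.running_mean
            arrays[f"bn_{j}_var"] = bn.running_var
        return arrays

    # ------------------------------------------------------------- encoding

    def encode_chain(self, chain: ResidueChain,
                     embedding: EmbeddingMatrix) -> ChainEncoding:
        """Build the constant per-chain inputs for both branches.

        The caller is responsible for the consistency filter; this method
        asserts it, since mismatched lengths cannot be encoded.
        """
        if len(chain) != embedding.length:
            raise ValueError(
                f"chain {chain.chain_id}: length {len(chain)} != embedding "
                f"rows {embedding.length} (failed consistency)"
            )
        cfg = self.config
        padded = pad(embedding, cfg.max_length)
        dist = distance_matrix(chain)
        adj = build_contact_map(dist, cfg.contact_threshold)
        a_norm = normalize_adjacency(adj)
        if cfg.node_feature_source == "embedding":
            node_x = embedding.values
        elif cfg.node_feature_source == "onehot":
            node_x = _onehot(chain.sequence)
        else:
            node_x = adj.sum(axis=1, dtype=float)[:, None]
        z = adjacency_power_features(a_norm, node_x, cfg.tag_k)
        return ChainEncoding(chain.chain_id, padded.values, z,
                             padded.true_length)

    # -------------------------------------------------------------- forward

    def forward_pairs(self, encodings: list[tuple[ChainEncoding, ChainEncoding]],
                      training: bool) -> Tensor:
        """Score a batch of (receptor, peptide) encodings -> (B, 1) logits."""
        chains = [c for pair in encodings for c in pair]  # rec1, pep1, rec2, ...
        padded = np.stack([c.padded for c in chains])
        f_seq = self.seq_encoder.forward_batch(padded)            # (2B, F)
        f_struct = self.graph_encoder.forward_batch(
            [c.power_features for c in chains])                   # (2B, F)
        w = self.config.fusion_weight
        fused = f_struct * (1.0 - w) + f_seq * w
        b = len(encodings)
        fused_rec = fused[0 : 2 * b : 2]
        fused_pep = fused[1 : 2 * b : 2]
        x = concat([fused_rec, fused_pep], axis=1)                # (B, 2F)
        return self.head.forward(x, training)

    def predict_scores(
        self, encodings: list[tuple[ChainEncoding, ChainEncoding]]
    ) -> np.ndarray:
        logits = self.forward_pairs(encodings, training=False).data.ravel()
        return 1.0 / (1.0 + np.exp(-logits))

    def predict(self, encoding_pair: tuple[ChainEncoding, ChainEncoding]
                ) -> Prediction:
        score = float(self.predict_scores([encoding_pair])[0])
        score = min(max(score, 1e-12), 1.0 - 1e-12)
        return Prediction(score)

    # ------------------------------------------------------------ checkpoint

    def save(self, path, seed: int | None = None,
             manifest_hash: str | None = None) -> None:
        """Single-file .npz checkpoint: parameters, BN stats, config, seed."""
        meta = {
            "config": self.config.to_dict(),
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed if seed is None else seed,
            "manifest_hash": manifest_hash,
        }
        np.savez(path, __meta__=json.dumps(meta), **self.named_arrays())

    @classmethod
    def load(cls, path) -> "PepPIModel":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["__meta__"]))
            model = cls(RunConfig.from_dict(meta["config"]))
            for i, p in enumerate(model.parameters()):
                p.data = archive[f"param_{i}"].copy()
            for j, bn in enumerate(model.head.norms):
                bn.running_mean = archive[f"bn_{j}_mean"].copy()
                bn.running_var = archive[f"bn_{j}_var"].copy()
        return model
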