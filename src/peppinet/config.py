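"""Run configuration: every tunable of the pipeline in one dataclass.

Defaults follow the published architecture: 1024-dim per-residue embeddings,
sequences padded to 1200, three conv(k=3)/pool(3) stages with 128 channels,
a single topology-adaptive graph convolution with K=3 polynomial filters,
128-dim branch features fused with weight ``w``, a 256->128->64->1 BN-ReLU
head, and Adam at lr 0.001, batch 32, 50 epochs.  The contact-map cutoff and
representative atom are not fixed by the architecture; they default to
10.0 Angstrom on C-alpha and are recorded in all output metadata.

``RunConfig.test_profile()`` shrinks the widths (d=16, L_max=60, 32
channels) so an end-to-end train/evaluate cycle runs in seconds on one CPU;
the architecture and its shape arithmetic are unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # structures
    contact_threshold: float = 10.0        # Angstrom
    representative_atom: str = "CA"        # CA | CB
    # embeddings
    embedding_dim: int = 1024
    embedding_provider: str = "synthetic"
    embedding_seed: int = 0
    max_length: int = 1200                 # L_max for zero padding
    # sequence branch
    conv_channels: int = 128
    kernel_size: int = 3
    pool_size: int = 3
    # graph branch
    tag_k: int = 3
    tag_channels: int = 128                # TAGCN output filters
    node_feature_source: str = "embedding"  # embedding | onehot | degree
    feature_dim: int = 128                 # per-branch feature vector size
    # fusion / head
    fusion_weight: float = 0.5
    head_widths: tuple[int, ...] = (128, 64)
    # training
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 50
    seed: int = 0
    # evaluation
    n_folds: int = 5
    threshold: float = 0.5
    # paths (CLI only; unused by the library API)
    paths: dict = field(default_factory=dict)

    @classmethod
    def test_profile(cls, **overrides) -> "RunConfig":
        """A small-width profile for fast CPU runs; same architecture."""
        base = dict(
            embedding_dim=16,
            max_length=60,
            conv_channels=32,
            tag_channels=32,
            feature_dim=32,
            head_widths=(32, 16),
            epochs=25,
        )
        base.update(overrides)
        return cls(**base)

    # ------------------------------------------------------------- (de)serde

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["head_widths"] = list(self.head_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kw = {k: v for k, v in d.items() if k in known}
        if "head_widths" in kw:
            kw["head_widths"] = tuple(kw["head_widths"])
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        if self.contact_threshold <= 0:
            raise ValueError("contact_threshold must be positive")
        if not 0.0 <= self.fusion_weight <= 1.0:
            raise ValueError("fusion_weight must lie in [0, 1]")
        if self.tag_k < 1:
            raise ValueError("tag_k must be >= 1")
        if self.node_feature_source not in ("embedding", "onehot", "degree"):
            raise ValueError(
                "node_feature_source must be 'embedding', 'onehot' or 'degree'")
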