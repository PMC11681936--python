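"""Topology-adaptive graph convolution over residue contact graphs.

A single TAGCN layer applies, per output filter f, a degree-K polynomial in
the normalized adjacency:

    y_f = sum_c ( sum_{k=0..K} g_{c,f,k} A_norm^k ) x_c + b_f 1,

followed by an elementwise nonlinearity (ReLU here).  A_norm^0 is the
identity, so K-hop locality holds exactly: a node's output depends only on
input features within K hops.  The node outputs are max-pooled per channel
and projected by a linear layer to the fixed-size structural feature vector
(128 dimensions at full scale).

Two call styles coexist: the pure functions :func:`tag_conv` /
:func:`pool_project` on explicit parameter containers (used by the oracle
tests), and the trainable :class:`GraphEncoder` whose parameters are
autodiff tensors.  Both compute the same polynomial; the trainable path
pre-multiplies the adjacency powers into the node features once per graph,
since adjacency and input features are constants during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat

__all__ = [
    "TagConvParams",
    "StructFeature",
    "tag_conv",
    "pool_project",
    "adjacency_power_features",
    "GraphEncoder",
]


@dataclass
class TagConvParams:
    """Polynomial filter coefficients g[c, f, k], k = 0..K, and bias b[f]."""

    coefficients: np.ndarray  # (C_in, F, K+1)
    bias: np.ndarray          # (F,)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.coefficients.ndim != 3:
            raise ValueError("coefficients must have shape (C_in, F, K+1)")
        if self.bias.shape != (self.coefficients.shape[1],):
            raise ValueError("bias length must equal the number of filters")
        if self.coefficients.shape[2] < 2:
            raise ValueError("polynomial order K must be >= 1")
        if not (np.all(np.isfinite(self.coefficients))
                and np.all(np.isfinite(self.bias))):
            raise ValueError("parameters must be finite")

    @property
    def k(self) -> int:
        return self.coefficients.shape[2] - 1

    @property
    def in_channels(self) -> int:
        return self.coefficients.shape[0]

    @property
    def out_channels(self) -> int:
        return self.coefficients.shape[1]


@dataclass
class StructFeature:
    """Fixed-size structural feature vector for one chain."""

    values: np.ndarray
    source_length: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def tag_conv(
    normalized_adjacency: np.ndarray,
    node_features: np.ndarray,
    params: TagConvParams,
    activation: str = "relu",
) -> np.ndarray:
    """Apply one TAGCN layer; returns (L, out_channels) node features."""
    a = np.asarray(normalized_adjacency, dtype=float)
    x = np.asarray(node_features, dtype=float)
    if a.shape[0] != a.shape[1] or a.shape[0] != x.shape[0]:
        raise ValueError(
            f"shape mismatch: adjacency {a.shape}, features {x.shape}"
        )
    if x.shape[1] != params.in_channels:
        raise ValueError(
            f"feature channels {x.shape[1]} != params in_channels "
            f"{params.in_channels}"
        )
    # Propagate features through increasing powers: p_k = A^k X.
    powers = [x]
    for _ in range(params.k):
        powers.append(a @ powers[-1])
    y = np.zeros((x.shape[0], params.out_channels))
    for k, p_k in enumerate(powers):
        y += p_k @ params.coefficients[:, :, k]
    y += params.bias
    if activation == "relu":
        return np.maximum(y, 0.0)
    if activation == "identity":
        return y
    raise ValueError(f"unknown activation {activation!r}")


def pool_project(
    node_features: np.ndarray,
    weight: np.ndarray,
    bias: np.ndarray | None = None,
) -> StructFeature:
    """Per-channel max over nodes, then affine projection to the feature dim."""
    x = np.asarray(node_features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("node_features must be a non-empty 2-D matrix")
    pooled = x.max(axis=0)
    out = pooled @ np.asarray(weight, dtype=float)
    if bias is not None:
        out = out + np.asarray(bias, dtype=float)
    return StructFeature(out, source_length=x.shape[0])


def adjacency_power_features(
    normalized_adjacency: np.ndarray, node_features: np.ndarray, k: int
) -> np.ndarray:
    """Stack [X, AX, ..., A^K X] -> (L, (K+1)*C); constant per graph.

    With this stacking, the TAGCN layer is a single dense product with the
    (K+1)*C x F coefficient matrix — the exact same polynomial, but the
    graph propagation is done once instead of on every training step.
    """
    x = np.asarray(node_features, dtype=float)
    a = np.asarray(normalized_adjacency, dtype=float)
    blocks = [x]
    for _ in range(k):
        blocks.append(a @ blocks[-1])
    return np.concatenate(blocks, axis=1)


class GraphEncoder:
    """Trainable single-layer TAGCN + max pool + linear projection."""

    def __init__(self, in_channels: int, tag_channels: int, feature_dim: int,
                 k: int, rng: np.random.Generator):
        self.k = k
        self.in_channels = in_channels
        scale = 1.0 / np.sqrt(in_channels * (k + 1))
        self.g = Tensor(
            rng.normal(0.0, scale, size=((k + 1) * in_channels, tag_channels)),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(tag_channels), requires_grad=True)
        self.proj_w = Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(tag_channels),
                       size=(tag_channels, feature_dim)),
            requires_grad=True,
        )
        self.proj_b = Tensor(np.zeros(feature_dim), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.g, self.b, self.proj_w, self.proj_b]

    def tag_params(self) -> TagConvParams:
        """Expose the stacked coefficients in (C_in, F, K+1) layout."""
        coeff = self.g.data.reshape(self.k + 1, self.in_channels, -1)
        return TagConvParams(coeff.transpose(1, 2, 0), self.b.data.copy())

    def forward_one(self, power_features: np.ndarray) -> Tensor:
        """Encode one chain from its precomputed [X, AX, ..., A^K X] stack."""
        z = Tensor(power_features)
        h = (z @ self.g + self.b).relu()          # (L, tag_channels)
        pooled = h.max(axis=0, keepdims=True)     # (1, tag_channels)
        return pooled @ self.proj_w + self.proj_b  # (1, feature_dim)

    def forward_batch(self, power_features: list[np.ndarray]) -> Tensor:
        return concat([self.forward_one(z) for z in power_features], axis=0)
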