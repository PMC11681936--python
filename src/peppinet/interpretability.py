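"""Post-hoc explanations: node importance and first-conv activation maps.

*Node importance* scores the residues of one chain by how much each
contributes to the structural readout.  The graph branch's per-node outputs
h_i pass through a single-head additive attention,

    alpha_i = softmax_i( u . tanh(W h_i) ),

whose weights (W, u) belong to an auxiliary explainer, not to the
predictor.  By default the explainer is fitted post hoc — attention-pooled
node features are trained to approximate the model's own max-pool readout —
so explaining a model never changes its predictions.  Scores sum to one and
permute with the nodes.

*Activation maps* expose the sequence branch: the raw (pre-ReLU) output of
the first convolution, position by position and channel by channel, plus the
top-k entries by absolute value.  Positions are 1-based in the conv-output
coordinate; position i corresponds to the residue window [i, i+kernel-1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor, softmax
from .graph_encoder import tag_conv
from .model import PepPIModel
from .structures_io import ContactGraph

__all__ = [
    "NodeImportance",
    "ActivationMap",
    "AttentionExplainer",
    "fit_node_attention",
    "node_importance",
    "activation_map",
    "write_importance_tsv",
]


@dataclass
class NodeImportance:
    """Per-residue importance, aligned to 1-based sequence positions."""

    scores: np.ndarray
    normalization: str = "softmax"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    def top_positions(self, k: int = 5) -> list[int]:
        order = np.argsort(-self.scores, kind="stable")
        return [int(i) + 1 for i in order[:k]]


@dataclass
class ActivationMap:
    """First-convolution activations and the top-k |value| entries."""

    values: np.ndarray                       # (width, channels), pre-ReLU
    top: list[tuple[int, int, float]] = field(default_factory=list)
    kernel: int = 3                          # for residue-window mapping

    def residue_window(self, position: int) -> tuple[int, int]:
        """Map a 1-based conv position to its residue span [i, i+k-1]."""
        if not 1 <= position <= self.values.shape[0]:
            raise ValueError("position outside activation width")
        return (position, position + self.kernel - 1)


class AttentionExplainer:
    """Additive attention over node features; parameters are auxiliary."""

    def __init__(self, feature_dim: int, hidden: int = 16, seed: int = 0):
        rng = np.random.default_rng(np.random.PCG64(seed))
        self.w = Tensor(rng.normal(0, 1 / np.sqrt(feature_dim),
                                   size=(feature_dim, hidden)),
                        requires_grad=True)
        self.u = Tensor(rng.normal(0, 1 / np.sqrt(hidden), size=(hidden, 1)),
                        requires_grad=True)
        self.fitted = False

    def parameters(self) -> list[Tensor]:
        return [self.w, self.u]

    def attention(self, node_features: np.ndarray) -> Tensor:
        h = Tensor(np.asarray(node_features, dtype=float))
        logits = (h @ self.w).tanh() @ self.u          # (L, 1)
        return softmax(logits, axis=0)


def _graph_node_outputs(graph: ContactGraph, model: PepPIModel) -> np.ndarray:
    """Post-activation TAGCN node features h (L x tag_channels)."""
    return tag_conv(graph.normalized, graph.node_features,
                    model.graph_encoder.tag_params(), activation="relu")


def fit_node_attention(model: PepPIModel, graphs: list[ContactGraph],
                       steps: int = 200, lr: float = 0.05,
                       seed: int = 0) -> AttentionExplainer:
    """Fit the explainer so attention pooling mimics the max-pool readout.

    Minimizes sum over graphs of || sum_i alpha_i h_i - max_i h_i ||^2.
    The predictor is untouched; only (W, u) are optimized.
    """
    feats = [_graph_node_outputs(g, model) for g in graphs]
    explainer = AttentionExplainer(feats[0].shape[1], seed=seed)
    opt = Adam(explainer.parameters(), lr=lr)
    for _ in range(steps):
        opt.zero_grad()
        total = None
        for h in feats:
            alpha = explainer.attention(h)               # (L, 1)
            pooled = (Tensor(h) * alpha).sum(axis=0)     # (C,)
            target = Tensor(h.max(axis=0))
            diff = pooled - target
            term = (diff * diff).sum()
            total = term if total is None else total + term
        total.backward()
        opt.step()
    explainer.fitted = True
    return explainer


def node_importance(chain_graph: ContactGraph, model: PepPIModel,
                    explainer: AttentionExplainer | None = None
                    ) -> NodeImportance:
    """Softmax attention scores over the chain's residues; sums to one."""
    h = _graph_node_outputs(chain_graph, model)
    if explainer is None:
        explainer = AttentionExplainer(h.shape[1], seed=model.config.seed)
    alpha = explainer.attention(h).data.ravel()
    tag = "softmax(fitted)" if explainer.fitted else "softmax(init)"
    return NodeImportance(alpha, normalization=tag)


def activation_map(sequence: str, model: PepPIModel, provider,
                   top_k: int = 20) -> ActivationMap:
    """First-conv activation values for one sequence, with the top-k list.

    Entries are (1-based position, 1-based channel, value), ranked by
    absolute value descending; exact ties resolve by position then channel.
    top_k larger than the number of entries returns them all.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    from .embeddings import pad

    emb = provider.embed(sequence)
    padded = pad(emb, model.config.max_length)
    values = model.seq_encoder.first_conv(padded.values)  # (W, C)
    w, c = values.shape
    flat = [(-abs(values[i, j]), i + 1, j + 1, float(values[i, j]))
            for i in range(w) for j in range(c)]
    flat.sort()
    top = [(pos, ch, val) for _, pos, ch, val in flat[:top_k]]
    return ActivationMap(values, top, kernel=model.config.kernel_size)


def write_importance_tsv(path, importance: NodeImportance,
                         sequence: str) -> None:
    """TSV of (1-based position, residue letter, score)."""
    with open(path, "w") as fh:
        fh.write("position\tresidue\tscore\n")
        for i, (ch, s) in enumerate(zip(sequence, importance.scores), start=1):
            fh.write(f"{i}\t{ch}\t{s:.6g}\n")
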