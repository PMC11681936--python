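"""Feature fusion and the BN-ReLU classification head.

Per chain, the structural and sequence feature vectors are blended with a
scalar weight w in [0, 1]:

    F_fused = (1 - w) * F_struct + w * F_seq.

The two chains' fused vectors are concatenated and classified by a stack of
three linear layers; the first two are each followed by batch normalization
and then ReLU (BN *before* the rectifier), and the last produces a single
logit passed through a sigmoid.  Scores >= 0.5 are labelled interacting.
The two reported confidences are (score, 1 - score).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = ["FusedFeature", "Prediction", "fuse", "BatchNorm", "PredictionHead",
           "classify"]

DECISION_THRESHOLD = 0.5


@dataclass
class FusedFeature:
    """Weighted blend of one chain's structure and sequence features."""

    values: np.ndarray
    w: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fused values must be finite")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"fusion weight must lie in [0, 1], got {self.w}")


@dataclass
class Prediction:
    """Sigmoid score with the derived label and confidence pair."""

    score: float

    def __post_init__(self):
        if not 0.0 < self.score < 1.0:
            raise ValueError("score must lie strictly in (0, 1)")

    @property
    def label(self) -> int:
        return int(self.score >= DECISION_THRESHOLD)

    @property
    def confidence_positive(self) -> float:
        return self.score

    @property
    def confidence_negative(self) -> float:
        return 1.0 - self.score


def fuse(f_struct, f_seq, w: float) -> FusedFeature:
    """Blend structural and sequence features: (1-w)*Fg + w*Fs."""
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"fusion weight must lie in [0, 1], got {w}")
    fg = np.asarray(getattr(f_struct, "values", f_struct), dtype=float).ravel()
    fs = np.asarray(getattr(f_seq, "values", f_seq), dtype=float).ravel()
    if fg.shape != fs.shape:
        raise ValueError(
            f"feature dimensions differ: {fg.shape} vs {fs.shape}"
        )
    return FusedFeature((1.0 - w) * fg + w * fs, w)


class BatchNorm:
    """1-D batch normalization over the batch axis with running statistics."""

    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.momentum = momentum
        self.eps = eps

    def parameters(self) -> list[Tensor]:
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            centred = x - mu
            var = (centred * centred).mean(axis=0, keepdims=True)
            n = x.shape[0]
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased)
            return self.gamma * (centred / (var + self.eps).sqrt()) + self.beta
        mu = Tensor(self.running_mean)
        sd = Tensor(np.sqrt(self.running_var + self.eps))
        return self.gamma * ((x - mu) / sd) + self.beta


class PredictionHead:
    """Three linear layers; BN-then-ReLU after the first two, sigmoid last."""

    def __init__(self, in_dim: int, hidden: tuple[int, ...],
                 rng: np.random.Generator):
        if len(hidden) != 2:
            raise ValueError("head expects exactly two hidden widths")
        dims = [in_dim, *hidden, 1]
        self.linears: list[tuple[Tensor, Tensor]] = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            w = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d_in), size=(d_in, d_out)),
                       requires_grad=True)
            b = Tensor(np.zeros(d_out), requires_grad=True)
            self.linears.append((w, b))
        self.norms = [BatchNorm(h) for h in hidden]
        # Structural record of the layer sequence, in execution order.
        self.layer_order = [
            "linear", "batchnorm", "relu",
            "linear", "batchnorm", "relu",
            "linear", "sigmoid",
        ]

    def parameters(self) -> list[Tensor]:
        params = [t for pair in self.linears for t in pair]
        for bn in self.norms:
            params.extend(bn.parameters())
        return params

    def forward(self, x: Tensor, training: bool) -> Tensor:
        """(B, in_dim) fused pair features -> (B, 1) logits."""
        for (w, b), bn in zip(self.linears[:-1], self.norms):
            x = bn(x @ w + b, training)
            x = x.relu()
        w, b = self.linears[-1]
        return x @ w + b


def classify(pair: tuple[FusedFeature, FusedFeature],
             head: PredictionHead) -> Prediction:
    """Score one (receptor, peptide) fused pair at inference (running BN)."""
    rec, pep = pair
    x = Tensor(np.concatenate([rec.values, pep.values])[None, :])
    logit = head.forward(x, training=False).data.item()
    score = float(1.0 / (1.0 + np.exp(-logit)))
    score = min(max(score, 1e-12), 1.0 - 1e-12)  # keep strictly inside (0,1)
    return Prediction(score)
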