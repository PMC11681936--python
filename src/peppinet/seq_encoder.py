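"""Convolutional sequence branch (TextCNN).

Three (conv, max-pool) stages over the zero-padded L_max x d embedding:
kernel size 3, stride 1, no padding for each convolution (so width shrinks
by 2), followed by non-overlapping max pooling with step 3 (floor
division).  At the default L_max = 1200 the widths are

    1200 -conv3-> 1198 -pool3-> 399 -conv3-> 397 -pool3-> 132
         -conv3-> 130 -pool3-> 43,

each stage carrying 128 channels; a final global max-pool over the 43
surviving positions yields the fixed 128-dim local-sequence feature vector.
Zero-padded positions are convolved like real ones (pad-then-convolve); the
global max is taken over the full width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, conv1d, maxpool1d
from .embeddings import PaddedEmbedding

__all__ = ["SeqFeature", "stage_widths", "TextCNN", "textcnn_forward"]


@dataclass
class SeqFeature:
    """Fixed-size local-sequence feature vector for one chain."""

    values: np.ndarray
    true_length: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def stage_widths(l_max: int, kernel: int = 3, pool: int = 3,
                 n_stages: int = 3) -> list[int]:
    """Widths after each conv and pool: [w1_conv, w1_pool, w2_conv, ...].

    Conv width is w - kernel + 1; pool width is floor(w / pool).  Raises if
    any stage input is shorter than the kernel or pools to zero.
    """
    widths = []
    w = l_max
    for stage in range(n_stages):
        if w < kernel:
            raise ValueError(
                f"stage {stage + 1} input width {w} shorter than kernel {kernel}"
            )
        w = w - kernel + 1
        widths.append(w)
        w = w // pool
        if w < 1:
            raise ValueError(f"stage {stage + 1} pools to zero width")
        widths.append(w)
    return widths


class TextCNN:
    """Trainable three-stage conv/pool encoder with a global-max readout."""

    def __init__(self, in_dim: int, channels: int, rng: np.random.Generator,
                 kernel: int = 3, pool: int = 3, n_stages: int = 3):
        self.kernel = kernel
        self.pool = pool
        self.n_stages = n_stages
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        c_in = in_dim
        for _ in range(n_stages):
            scale = 1.0 / np.sqrt(kernel * c_in)
            self.weights.append(
                Tensor(rng.normal(0.0, scale, size=(kernel, c_in, channels)),
                       requires_grad=True)
            )
            self.biases.append(Tensor(np.zeros(channels), requires_grad=True))
            c_in = channels
        self.channels = channels

    def parameters(self) -> list[Tensor]:
        return [t for pair in zip(self.weights, self.biases) for t in pair]

    def forward_batch(self, padded: np.ndarray) -> Tensor:
        """(B, L_max, d) padded embeddings -> (B, channels) features."""
        if padded.ndim != 3:
            raise ValueError("expected a (B, L_max, d) batch")
        stage_widths(padded.shape[1], self.kernel, self.pool, self.n_stages)
        h = Tensor(padded)
        for w, b in zip(self.weights, self.biases):
            h = conv1d(h, w, b).relu()
            h = maxpool1d(h, self.pool)
        return h.max(axis=1)  # global max over remaining positions

    def first_conv(self, padded: np.ndarray) -> np.ndarray:
        """Raw first-convolution output (pre-ReLU) for activation maps."""
        h = conv1d(Tensor(padded[None, :, :]), self.weights[0], self.biases[0])
        return h.data[0]


def textcnn_forward(padded: PaddedEmbedding, model: TextCNN) -> SeqFeature:
    """Encode one padded embedding to its fixed-size sequence feature."""
    out = model.forward_batch(padded.values[None, :, :])
    return SeqFeature(out.data[0], true_length=padded.true_length)
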