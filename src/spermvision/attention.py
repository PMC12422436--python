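"""Convolutional Block Attention — functional form on plain arrays.

CBAM refines a feature map F (C, H, W) in two sequential steps:

* channel attention: M_c = sigmoid(MLP(GAP(F)) + MLP(GMP(F))), with global
  average/max pooling over the spatial dimensions and a shared one-hidden-
  layer ReLU MLP (no biases);
* spatial attention: M_s = sigmoid(conv7x7([mean_c(F') ; max_c(F')])),
  a single 7x7 convolution (padding 3) over the channel-mean and
  channel-max planes.

F' = M_c ⊙ F (broadcast per channel) and F'' = M_s ⊙ F' (broadcast per
location), so both masks only attenuate: |F''| <= |F| element-wise.

These functions are the ground-truth definition used by tests; the
trainable :class:`spermvision.nn.CBAM` layer computes the same math on
autodiff tensors and is checked against this form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CbamWeights", "channel_attention", "spatial_attention", "cbam_refine"]


@dataclass
class CbamWeights:
    """Weights of one CBAM block.

    mlp_w1 : (C, C//r) first (shared) MLP layer
    mlp_w2 : (C//r, C) second MLP layer
    spatial_kernel : (2, 7, 7) conv weights over the [avg; max] planes
    spatial_bias : scalar conv bias
    reduction_r : channel reduction ratio r
    """

    mlp_w1: np.ndarray
    mlp_w2: np.ndarray
    spatial_kernel: np.ndarray
    spatial_bias: float
    reduction_r: int

    def __post_init__(self):
        c, hidden = self.mlp_w1.shape
        if c % self.reduction_r or hidden != c // self.reduction_r:
            raise ValueError(
                f"MLP shapes inconsistent with reduction: C={c}, hidden={hidden}, r={self.reduction_r}"
            )
        if self.spatial_kernel.shape != (2, 7, 7):
            raise ValueError(f"spatial kernel must be (2, 7, 7), got {self.spatial_kernel.shape}")

    @classmethod
    def initialize(cls, channels: int, reduction: int, rng: np.random.Generator) -> "CbamWeights":
        """Neutral-start weights: Kaiming-uniform hidden layer, zero output
        layer and spatial kernel, so both masks begin at exactly 0.5."""
        hidden = channels // reduction
        b1 = np.sqrt(6.0 / channels)
        return cls(
            mlp_w1=rng.uniform(-b1, b1, (channels, hidden)),
            mlp_w2=np.zeros((hidden, channels)),
            spatial_kernel=np.zeros((2, 7, 7)),
            spatial_bias=0.0,
            reduction_r=reduction,
        )


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _check_map(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 3:
        raise ValueError(f"feature map must be (C, H, W), got shape {f.shape}")
    return f


def channel_attention(f: np.ndarray, w: CbamWeights) -> np.ndarray:
    """Channel mask M_c in (0,1)^C for a single (C, H, W) feature map."""
    f = _check_map(f)
    c = f.shape[0]
    if w.mlp_w1.shape[0] != c:
        raise ValueError(f"channel mismatch: map has {c} channels, MLP expects {w.mlp_w1.shape[0]}")
    gap = f.mean(axis=(1, 2))
    gmp = f.max(axis=(1, 2))

    def mlp(x):
        return np.maximum(x @ w.mlp_w1, 0.0) @ w.mlp_w2

    return _sigmoid(mlp(gap) + mlp(gmp))


def spatial_attention(fp: np.ndarray, w: CbamWeights) -> np.ndarray:
    """Spatial mask M_s in (0,1)^{H x W} for a single (C, H, W) map."""
    fp = _check_map(fp)
    planes = np.stack([fp.mean(axis=0), fp.max(axis=0)])  # (2, H, W)
    padded = np.pad(planes, ((0, 0), (3, 3), (3, 3)))
    h, wdt = fp.shape[1:]
    out = np.empty((h, wdt))
    for i in range(h):
        for j in range(wdt):
            out[i, j] = np.sum(padded[:, i : i + 7, j : j + 7] * w.spatial_kernel)
    return _sigmoid(out + w.spatial_bias)


def cbam_refine(f: np.ndarray, w: CbamWeights) -> np.ndarray:
    """Full CBAM refinement F -> F'' = M_s ⊙ (M_c ⊙ F); shape preserved."""
    f = _check_map(f)
    fp = channel_attention(f, w)[:, None, None] * f
    return spatial_attention(fp, w)[None, :, :] * fp
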