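"""Three-stage image preprocessing: enhance -> denoise -> sharpen.

The stages are

1. contrast enhancement by min-max histogram stretching,
   I_enh = (I - min I) / (max I - min I), applied jointly over channels;
2. Gaussian smoothing, I_den = I_enh * G, a normalized discrete Gaussian
   kernel with reflect padding;
3. unsharp masking, I_sharp = I_den + alpha * (I_den - I_den * G_sigma),
   clipped back to [0, 1].

Kernel sizes, sigmas and alpha are free parameters of the source method;
the defaults here are standard unsharp-masking practice and every value
is overridable through :class:`PreprocessConfig`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _skimage_resize

__all__ = [
    "PreprocessConfig", "gaussian_kernel", "enhance", "denoise", "sharpen",
    "preprocess_pipeline", "to_network_input",
]


@dataclass(frozen=True)
class PreprocessConfig:
    denoise_sigma: float = 1.0
    denoise_ksize: int = 5
    sharpen_alpha: float = 1.5
    sharpen_sigma: float = 2.0
    resize_to: int | None = 224

    def __post_init__(self):
        if self.denoise_ksize < 3 or self.denoise_ksize % 2 == 0:
            raise ValueError(f"denoise_ksize must be odd and >= 3, got {self.denoise_ksize}")
        if self.denoise_sigma <= 0 or self.sharpen_sigma <= 0:
            raise ValueError("sigmas must be > 0")
        if self.sharpen_alpha < 0:
            raise ValueError("sharpen_alpha must be >= 0")


def gaussian_kernel(sigma: float, ksize: int) -> np.ndarray:
    """Normalized 2-D Gaussian kernel (weights sum to exactly 1)."""
    half = ksize // 2
    ax = np.arange(-half, half + 1, dtype=float)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def enhance(img: np.ndarray) -> np.ndarray:
    """Min-max stretch to [0, 1] jointly over all channels."""
    img = np.asarray(img, dtype=float)
    if img.size == 0:
        raise ValueError("cannot enhance an empty image")
    lo, hi = img.min(), img.max()
    if hi == lo:
        warnings.warn("constant image: histogram stretch undefined, returning zeros")
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def _conv_channels(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    if img.ndim == 2:
        return ndimage.convolve(img, kernel, mode="reflect")
    return np.stack(
        [ndimage.convolve(img[..., c], kernel, mode="reflect") for c in range(img.shape[-1])],
        axis=-1,
    )


def denoise(img: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Gaussian smoothing with reflect padding; constant images are fixed points."""
    img = np.asarray(img, dtype=float)
    side = min(img.shape[:2])
    if cfg.denoise_ksize > side:
        raise ValueError(
            f"denoise kernel size {cfg.denoise_ksize} exceeds image side {side}"
        )
    return _conv_channels(img, gaussian_kernel(cfg.denoise_sigma, cfg.denoise_ksize))


def sharpen(img: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Unsharp masking: I + alpha*(I - blur(I)), clipped to [0, 1]."""
    img = np.asarray(img, dtype=float)
    ksize = int(2 * round(3 * cfg.sharpen_sigma) + 1)
    ksize = max(3, min(ksize, min(img.shape[:2]) - (1 - min(img.shape[:2]) % 2)))
    if ksize % 2 == 0:
        ksize -= 1
    blurred = _conv_channels(img, gaussian_kernel(cfg.sharpen_sigma, ksize))
    return np.clip(img + cfg.sharpen_alpha * (img - blurred), 0.0, 1.0)


def preprocess_pipeline(img: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """enhance -> denoise -> sharpen -> optional bilinear resize."""
    out = sharpen(denoise(enhance(img), cfg), cfg)
    if cfg.resize_to is not None:
        shape = (cfg.resize_to, cfg.resize_to) + out.shape[2:]
        out = _skimage_resize(out, shape, order=1, mode="reflect", anti_aliasing=False)
    return out


def to_network_input(images, cfg: PreprocessConfig, input_size: int) -> np.ndarray:
    """Preprocess a list of grayscale/RGB images into an (N, 3, S, S) batch.

    Grayscale inputs are replicated to three channels, matching how RGB
    micrographs feed a three-channel backbone.
    """
    cfg = PreprocessConfig(
        denoise_sigma=cfg.denoise_sigma,
        denoise_ksize=cfg.denoise_ksize,
        sharpen_alpha=cfg.sharpen_alpha,
        sharpen_sigma=cfg.sharpen_sigma,
        resize_to=input_size,
    )
    batch = np.empty((len(images), 3, input_size, input_size))
    for i, img in enumerate(images):
        out = preprocess_pipeline(np.asarray(img), cfg)
        if out.ndim == 2:
            out = np.stack([out] * 3, axis=0)
        else:
            out = out.transpose(2, 0, 1)[:3]
        batch[i] = out
    return batch
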