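"""Interpretability: Grad-CAM heatmaps and 2-D feature embeddings.

Grad-CAM weights each channel of a chosen activation map by the spatial
mean of the gradient of the target-class logit with respect to that
activation, forms ReLU(sum_c w_c A_c), bilinearly upsamples to the input
size, and min-max normalizes (constant maps become all zeros).  The
default target layer is the final CBAM-refined map, the representation
that carries the attention refinement.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _resize

from .network import TrainedNetwork

__all__ = ["grad_cam", "normalize_heatmap", "overlay", "embed_2d"]


def normalize_heatmap(values: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; constant maps -> all zeros. Idempotent."""
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def grad_cam(trained: TrainedNetwork, image: np.ndarray, target_class: int,
             layer: str = "cbam") -> np.ndarray:
    """Class-saliency heatmap, shape = input H x W, values in [0, 1]."""
    net = trained.net
    net.eval()
    x = np.asarray(image, dtype=np.float64)
    if x.ndim == 3:
        x = x[None]
    if not 0 <= target_class < net.n_classes:
        raise ValueError(f"target class {target_class} outside [0, {net.n_classes})")
    out = net.forward(x, capture=True)
    if layer not in ("cbam", "conv5"):
        raise ValueError(f"unsupported Grad-CAM layer {layer!r}; use 'cbam' or 'conv5'")
    act = out[layer]
    if act is None:
        raise ValueError(f"layer {layer!r} produced no activation (is CBAM enabled?)")
    seed = np.zeros_like(out["logits"].data)
    seed[0, target_class] = 1.0
    out["logits"].backward(seed)
    grads = act.grad[0]                       # (C, H, W)
    weights = grads.mean(axis=(1, 2))         # channel-wise gradient means
    cam = np.maximum((weights[:, None, None] * act.data[0]).sum(axis=0), 0.0)
    size = net.cfg.input_size
    cam = _resize(cam, (size, size), order=1, mode="edge", anti_aliasing=False)
    return normalize_heatmap(cam)


def overlay(image: np.ndarray, heatmap: np.ndarray, opacity: float = 0.5) -> np.ndarray:
    """Alpha-blend a jet-colormapped heatmap onto a grayscale/RGB image."""
    from matplotlib import cm as _cm

    image = np.asarray(image, dtype=float)
    if image.ndim == 3 and image.shape[0] in (1, 3):   # CHW -> HW(C)
        image = image.transpose(1, 2, 0)
        if image.shape[2] == 1:
            image = image[..., 0]
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.shape[:2] != heatmap.shape:
        raise ValueError(f"size mismatch: image {image.shape[:2]} vs heatmap {heatmap.shape}")
    colored = _cm.jet(heatmap)[..., :3]
    return np.clip((1.0 - opacity) * image + opacity * colored, 0.0, 1.0)


def embed_2d(x: np.ndarray, seed: int = 0) -> np.ndarray:
    """Seeded t-SNE of feature rows to N x 2 coordinates."""
    from sklearn.manifold import TSNE

    x = np.asarray(getattr(x, "data", x), dtype=float)
    n = x.shape[0]
    if n < 5:
        raise ValueError(f"embedding requires at least 5 rows, got {n}")
    perplexity = min(30.0, (n - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=seed, perplexity=perplexity, init="pca")
    return tsne.fit_transform(x)


def save_triptych(image, heatmap, path, opacity: float = 0.5):
    """Original | heatmap | overlay panel figure (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.asarray(image, dtype=float)
    if img.ndim == 3 and img.shape[0] in (1, 3):
        img = img.transpose(1, 2, 0).squeeze()
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    axes[0].imshow(img, cmap="gray"); axes[0].set_title("original")
    axes[1].imshow(heatmap, cmap="jet"); axes[1].set_title("Grad-CAM")
    axes[2].imshow(overlay(image, heatmap, opacity)); axes[2].set_title("overlay")
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_scatter(coords, labels, class_names, path, title=""):
    """Class-colored 2-D embedding scatter plot (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = np.asarray(coords)
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for c, name in enumerate(class_names):
        m = labels == c
        ax.scatter(coords[m, 0], coords[m, 1], s=12, label=name)
    ax.legend(fontsize=7)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
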