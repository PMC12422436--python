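"""Seeded generator of sperm-like labeled image sets.

Two class schemes mirror the public sperm-head benchmarks:

* ``smids3`` — Normal Sperm (oval head + single tail), Abnormal Sperm
  (eccentric / doubled-ellipse head + tail), Non-Sperm (tail-less blob
  of debris);
* ``hushem4`` — the four head-shape morphologies: Normal (oval, axis
  ratio ~1.5), Tapered (elongated, ratio >= 2.5 at full deformation),
  Pyriform (two fused ellipses of unequal radii, pear-shaped),
  Amorphous (random-walk perturbed polygon).

Images are rendered grayscale on a noisy background with a mild
illumination gradient, heads brighter than tails so a simple intensity
threshold isolates the head.  Everything is a pure function of
:class:`SyntheticSpec`: identical specs give bit-identical datasets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

__all__ = [
    "SMIDS3_CLASSES", "HUSHEM4_CLASSES", "SyntheticSpec", "LabeledImageSet",
    "render_cell", "generate_dataset", "write_image_folder",
]

SMIDS3_CLASSES = ["Normal_Sperm", "Abnormal_Sperm", "Non_Sperm"]
HUSHEM4_CLASSES = ["Normal", "Tapered", "Pyriform", "Amorphous"]

_SCHEMES = {"smids3": SMIDS3_CLASSES, "hushem4": HUSHEM4_CLASSES}

HEAD_INTENSITY = 0.85
TAIL_INTENSITY = 0.45
BACKGROUND_LEVEL = 0.15


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one dataset; the dataset is a pure function of this."""

    scheme: str = "smids3"
    n_per_class: int = 10
    image_size: int = 128
    noise_sd: float = 0.05
    deform_strength: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in _SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; expected one of {sorted(_SCHEMES)}")
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.deform_strength <= 1.0:
            raise ValueError("deform_strength must be in [0, 1]")

    @property
    def class_names(self) -> list[str]:
        return list(_SCHEMES[self.scheme])


@dataclass
class LabeledImageSet:
    images: list  # H x W float arrays in [0, 1]
    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels out of range for class_names")

    def __len__(self):
        return len(self.images)


# --------------------------------------------------------------------- shapes

def _grid(size: int):
    y, x = np.mgrid[0:size, 0:size].astype(float)
    return x, y


def _soft_ellipse(x, y, cx, cy, a, b, angle, sharpness=1.5):
    """Anti-aliased filled ellipse via a smoothed implicit function."""
    ca, sa = np.cos(angle), np.sin(angle)
    xr = (x - cx) * ca + (y - cy) * sa
    yr = -(x - cx) * sa + (y - cy) * ca
    v = (xr / a) ** 2 + (yr / b) ** 2
    return np.clip((1.0 - v) * a / sharpness + 0.5, 0.0, 1.0)


def _soft_polygon(x, y, verts_x, verts_y, softness=1.5):
    """Filled polygon mask, softened by signed distance approximation."""
    from matplotlib.path import Path as MplPath

    pts = np.column_stack([x.ravel(), y.ravel()])
    poly = MplPath(np.column_stack([verts_x, verts_y]))
    inside = poly.contains_points(pts).reshape(x.shape).astype(float)
    # Soften edges with a tiny box blur to approximate anti-aliasing.
    from scipy.ndimage import uniform_filter

    return uniform_filter(inside, size=int(2 * softness) + 1)


def _bezier_tail(x, y, p0, p1, p2, width=1.6):
    """Quadratic Bezier stroke rendered as a soft tube of the given width."""
    t = np.linspace(0.0, 1.0, 240)[:, None]
    pts = ((1 - t) ** 2) * np.array(p0) + 2 * (1 - t) * t * np.array(p1) + t**2 * np.array(p2)
    canvas = np.zeros_like(x)
    size = x.shape[0]
    for px, py in pts:
        if not (0 <= px < size and 0 <= py < size):
            continue
        x0, x1 = int(max(px - 4, 0)), int(min(px + 5, size))
        y0, y1 = int(max(py - 4, 0)), int(min(py + 5, size))
        d2 = (x[y0:y1, x0:x1] - px) ** 2 + (y[y0:y1, x0:x1] - py) ** 2
        patch = np.clip(1.0 - np.sqrt(d2) / width, 0.0, 1.0)
        np.maximum(canvas[y0:y1, x0:x1], patch, out=canvas[y0:y1, x0:x1])
    return canvas


def _head_geometry(rng: np.random.Generator, size: int):
    cx = size / 2 + rng.uniform(-size * 0.06, size * 0.06)
    cy = size / 2 + rng.uniform(-size * 0.06, size * 0.06)
    angle = rng.uniform(0, np.pi)
    base = size * 0.16
    return cx, cy, angle, base


def _render_head(class_id, scheme, size, deform, rng, x, y):
    """Head mask plus the head boundary point where the tail attaches."""
    cx, cy, angle, base = _head_geometry(rng, size)
    if scheme == "smids3":
        kind = ["normal", "abnormal", "nonsperm"][class_id]
    else:
        kind = ["normal", "tapered", "pyriform", "amorphous"][class_id]

    if kind == "normal":
        a, b = base * 1.5, base
        head = _soft_ellipse(x, y, cx, cy, a, b, angle)
    elif kind == "tapered":
        ratio = 2.0 + 1.6 * deform  # >= 2.8 at the reference deformation 0.5
        a, b = base * ratio, base * 0.85
        head = _soft_ellipse(x, y, cx, cy, a, b, angle)
    elif kind == "pyriform":
        # Pear: large ellipse fused with a smaller one offset along the axis.
        a1, b1 = base * 1.3, base * 1.05
        a2, b2 = base * (0.9 - 0.3 * deform), base * (0.7 - 0.2 * deform)
        off = a1 * 0.9
        cx2 = cx + off * np.cos(angle)
        cy2 = cy + off * np.sin(angle)
        head = np.maximum(
            _soft_ellipse(x, y, cx, cy, a1, b1, angle),
            _soft_ellipse(x, y, cx2, cy2, a2, b2, angle),
        )
    elif kind == "amorphous":
        n_vert = 11
        theta = np.linspace(0, 2 * np.pi, n_vert, endpoint=False)
        radii = base * 1.2 * (1.0 + deform * rng.uniform(-0.55, 0.55, n_vert))
        # random-walk perturbation accumulates along the boundary
        walk = np.cumsum(rng.normal(0, deform * 0.18, n_vert))
        walk -= walk.mean()
        radii *= np.exp(walk)
        vx = cx + radii * np.cos(theta)
        vy = cy + radii * np.sin(theta)
        head = _soft_polygon(x, y, vx, vy)
    elif kind == "abnormal":
        # Eccentric doubled ellipse: two clearly separated overlapping heads.
        a, b = base * (1.1 + 0.4 * deform), base * 0.75
        off = base * (0.8 + 0.9 * deform)
        ang2 = angle + deform * rng.uniform(0.6, 1.3)
        cx2 = cx + off * np.cos(angle + np.pi / 3)
        cy2 = cy + off * np.sin(angle + np.pi / 3)
        head = np.maximum(
            _soft_ellipse(x, y, cx, cy, a, b, angle),
            _soft_ellipse(x, y, cx2, cy2, a * 0.9, b * 0.9, ang2),
        )
    else:  # nonsperm: large compact debris blob, no tail
        n_vert = 9
        theta = np.linspace(0, 2 * np.pi, n_vert, endpoint=False)
        radii = base * rng.uniform(1.1, 1.6) * (1.0 + rng.uniform(-0.2, 0.2, n_vert))
        vx = cx + radii * np.cos(theta)
        vy = cy + radii * np.sin(theta)
        head = _soft_polygon(x, y, vx, vy)

    # Tail attachment: rear of the head along its major axis.
    rear = (cx - np.cos(angle) * base * 1.5, cy - np.sin(angle) * base * 1.5)
    has_tail = kind not in ("nonsperm",)
    return head, rear, angle, has_tail


def render_cell(class_id: int, scheme: str, size: int, deform_strength: float,
                rng: np.random.Generator) -> np.ndarray:
    """Render one labeled cell image (H x W float array in [0, 1])."""
    names = _SCHEMES.get(scheme)
    if names is None:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {sorted(_SCHEMES)}")
    if not 0 <= class_id < len(names):
        raise ValueError(
            f"class_id {class_id} invalid for scheme {scheme!r} with classes {names}"
        )
    x, y = _grid(size)
    head, rear, angle, has_tail = _render_head(class_id, scheme, size, deform_strength, rng, x, y)

    img = np.full((size, size), BACKGROUND_LEVEL)
    # mild illumination gradient, exercises histogram stretching downstream
    gx, gy = rng.uniform(-1, 1, 2) * 0.05
    img += gx * (x / size - 0.5) + gy * (y / size - 0.5)

    if has_tail:
        tail_len = size * 0.32
        back = angle + np.pi + rng.uniform(-0.3, 0.3)
        p0 = rear
        p2 = (rear[0] + tail_len * np.cos(back), rear[1] + tail_len * np.sin(back))
        bend = rng.uniform(-0.25, 0.25) * tail_len
        mid = (
            (p0[0] + p2[0]) / 2 - bend * np.sin(back),
            (p0[1] + p2[1]) / 2 + bend * np.cos(back),
        )
        tail = _bezier_tail(x, y, p0, mid, p2)
        img = np.maximum(img, BACKGROUND_LEVEL + tail * (TAIL_INTENSITY - BACKGROUND_LEVEL))

    img = np.maximum(img, BACKGROUND_LEVEL + head * (HEAD_INTENSITY - BACKGROUND_LEVEL))
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: SyntheticSpec) -> LabeledImageSet:
    """Balanced, deterministically shuffled dataset for ``spec``."""
    rng = np.random.default_rng(spec.seed)
    names = spec.class_names
    images, labels = [], []
    for class_id in range(len(names)):
        for _ in range(spec.n_per_class):
            img = render_cell(class_id, spec.scheme, spec.image_size, spec.deform_strength, rng)
            if spec.noise_sd > 0:
                img = np.clip(img + rng.normal(0, spec.noise_sd, img.shape), 0.0, 1.0)
            images.append(img.astype(np.float64))
            labels.append(class_id)
    order = np.random.default_rng(spec.seed + 1).permutation(len(images))
    return LabeledImageSet(
        images=[images[i] for i in order],
        labels=np.array(labels)[order],
        class_names=names,
    )


def write_image_folder(image_set: LabeledImageSet, path) -> dict:
    """Write one PNG per image under ``path/<class_name>/``; return manifest."""
    path = Path(path)
    manifest: dict = {"class_names": image_set.class_names, "files": []}
    if len(image_set) == 0:
        path.mkdir(parents=True, exist_ok=True)
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    counters = {name: 0 for name in image_set.class_names}
    for img, label in zip(image_set.images, image_set.labels):
        name = image_set.class_names[label]
        cls_dir = path / name
        cls_dir.mkdir(parents=True, exist_ok=True)
        fname = f"{name}_{counters[name]:04d}.png"
        counters[name] += 1
        arr = np.clip(np.asarray(img) * 255.0, 0, 255).astype(np.uint8)
        PILImage.fromarray(arr).save(cls_dir / fname)
        manifest["files"].append({"file": f"{name}/{fname}", "label": int(label)})
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
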