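"""Dataset reading and run-configuration plumbing."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

from .synthetic import LabeledImageSet

__all__ = ["read_image_folder", "config_hash", "load_run_config"]

log = logging.getLogger("spermvision")

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp"}


def read_image_folder(path) -> LabeledImageSet:
    """Read a folder-per-class image tree into a labeled set.

    Classes are the sub-directory names sorted lexicographically; label
    ids follow that order.  Corrupt files are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset path {path} does not exist")
    class_dirs = sorted(d for d in path.iterdir() if d.is_dir())
    if len(class_dirs) < 2:
        raise ValueError(f"{path} has {len(class_dirs)} class sub-directories; need >= 2")
    images, labels = [], []
    skipped = 0
    for label, cls_dir in enumerate(class_dirs):
        files = sorted(p for p in cls_dir.iterdir()
                       if p.suffix.lower() in IMAGE_EXTENSIONS)
        if not files:
            raise ValueError(f"class directory {cls_dir.name!r} contains no readable images")
        for f in files:
            try:
                with PILImage.open(f) as im:
                    arr = np.asarray(im.convert("L"), dtype=np.float64) / 255.0
            except Exception as exc:  # corrupt file
                skipped += 1
                log.warning("skipping unreadable image %s (%s)", f, exc)
                continue
            images.append(arr)
            labels.append(label)
    if skipped:
        log.warning("skipped %d unreadable files", skipped)
    return LabeledImageSet(images=images, labels=np.array(labels),
                           class_names=[d.name for d in class_dirs])


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable run configuration."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def load_run_config(path) -> dict:
    """YAML or JSON run configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text)
    return json.loads(text)
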