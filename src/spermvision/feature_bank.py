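"""Deep feature extraction from a frozen trained network.

Five extraction sites are exposed, tagged by where in the network the
representation lives (C = final stage channel count, H x W its spatial
size):

========= ================================================== =========
tag       definition                                         dimension
========= ================================================== =========
cbam      flattened final CBAM-refined map (channel-major)   C*H*W
gap       spatial mean of the final refined map              C
gmp       spatial max of the final refined map               C
combined  [gap ; gmp] concatenation                          2C
prefinal  combined descriptor after head batch-norm (eval)   2C
backbone  spatial mean of the pre-CBAM final stage output    C
========= ================================================== =========

Extraction always runs in inference mode (dropout off, batch-norm on
running statistics), so repeated calls are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .network import TrainedNetwork

__all__ = ["LAYER_TAGS", "FeatureMatrix", "extract_features", "combine_gap_gmp",
           "save_feature_matrix", "load_feature_matrix"]

LAYER_TAGS = ("cbam", "gap", "gmp", "combined", "prefinal", "backbone")


@dataclass
class FeatureMatrix:
    data: np.ndarray           # (N, D), float32
    layer_tag: str
    sample_ids: list = field(default_factory=list)
    class_names: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if not self.sample_ids:
            self.sample_ids = list(range(self.data.shape[0]))
        if len(self.sample_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids but {self.data.shape[0]} rows"
            )

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def d(self) -> int:
        return self.data.shape[1]


def extract_features(trained: TrainedNetwork, x: np.ndarray, layer_tag: str,
                     batch_size: int = 32, sample_ids=None) -> FeatureMatrix:
    """Extract one tagged representation for every image in ``x``."""
    if layer_tag not in LAYER_TAGS:
        raise ValueError(f"unknown layer tag {layer_tag!r}; valid tags: {LAYER_TAGS}")
    net = trained.net
    net.eval()
    x = np.asarray(x, dtype=np.float64)
    rows = []
    for start in range(0, len(x), batch_size):
        out = net.forward(x[start : start + batch_size], capture=True)
        if layer_tag == "cbam":
            f = out["cbam"].data
            rows.append(f.reshape(f.shape[0], -1))     # channel-major flatten
        elif layer_tag == "gap":
            rows.append(out["gap"].data)
        elif layer_tag == "gmp":
            rows.append(out["gmp"].data)
        elif layer_tag == "combined":
            rows.append(out["combined"].data)
        elif layer_tag == "prefinal":
            rows.append(out["prefinal"].data)
        else:  # backbone: pooled pre-CBAM final stage output
            rows.append(out["conv5"].data.mean(axis=(2, 3)))
    return FeatureMatrix(np.concatenate(rows), layer_tag,
                         sample_ids=list(sample_ids) if sample_ids is not None else [],
                         class_names=trained.class_names)


def combine_gap_gmp(fgap: FeatureMatrix, fgmp: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation [gap ; gmp]; sample order must match."""
    if fgap.n != fgmp.n:
        raise ValueError(f"row mismatch: gap has {fgap.n} rows, gmp has {fgmp.n}")
    if fgap.sample_ids != fgmp.sample_ids:
        raise ValueError("sample_ids differ between gap and gmp matrices")
    return FeatureMatrix(np.concatenate([fgap.data, fgmp.data], axis=1), "combined",
                         sample_ids=list(fgap.sample_ids), class_names=fgap.class_names)


def save_feature_matrix(fm: FeatureMatrix, path):
    """NPY matrix plus JSON sidecar (tag, shape, class names)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path.with_suffix(".npy"), fm.data)
    path.with_suffix(".json").write_text(json.dumps({
        "layer_tag": fm.layer_tag,
        "shape": list(fm.data.shape),
        "sample_ids": list(map(int, fm.sample_ids)),
        "class_names": fm.class_names,
    }, indent=2))


def load_feature_matrix(path) -> FeatureMatrix:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return FeatureMatrix(np.load(path.with_suffix(".npy")), meta["layer_tag"],
                         sample_ids=meta["sample_ids"], class_names=meta["class_names"])
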