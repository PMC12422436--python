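"""Residual backbone with CBAM refinement and two-stage fine-tuning.

Architecture: a 7x7/stride-2 stem with max-pooling, four stages of
bottleneck residual blocks (the ``resnet50`` variant uses the canonical
[3,4,6,3] blocks and [256,512,1024,2048] stage widths; the ``tiny``
variant keeps the identical wiring at desk scale), a CBAM block after
the output of each stage, and a head that concatenates global average
and global max pooling of the final refined map (length 2C), applies
1-D batch norm, dropout, an affine layer and softmax.

Training runs in two phases: first the backbone is frozen (parameters
and batch-norm statistics untouched) while CBAM and the head learn at a
high rate, then everything is fine-tuned with a reduced backbone rate.
The loss is mean cross-entropy plus an L2 penalty lambda*||theta||^2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Adam, Tensor
from .nn import CBAM, BatchNorm1d, BatchNorm2d, Bottleneck, Conv2d, Dropout, Linear, Module

__all__ = [
    "BackboneConfig", "TrainConfig", "SpermNet", "TrainedNetwork",
    "build_network", "train_two_stage", "predict", "save_checkpoint", "load_checkpoint",
]

_VARIANTS = {
    "resnet50": dict(stage_blocks=[3, 4, 6, 3], stage_channels=[256, 512, 1024, 2048],
                     stem_channels=64, cbam_reduction=16),
    "tiny": dict(stage_blocks=[1, 1, 1, 1], stage_channels=[16, 32, 64, 128],
                 stem_channels=8, cbam_reduction=4),
}


@dataclass(frozen=True)
class BackboneConfig:
    variant: str = "tiny"
    stage_blocks: tuple = ()
    stage_channels: tuple = ()
    input_size: int = 64
    pretrained: bool = False

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {sorted(_VARIANTS)}")
        preset = _VARIANTS[self.variant]
        object.__setattr__(self, "stage_blocks", tuple(self.stage_blocks or preset["stage_blocks"]))
        object.__setattr__(self, "stage_channels", tuple(self.stage_channels or preset["stage_channels"]))
        if len(self.stage_blocks) != 4 or len(self.stage_channels) != 4:
            raise ValueError("backbone requires exactly 4 stages")

    @property
    def stem_channels(self) -> int:
        return _VARIANTS[self.variant]["stem_channels"]

    @property
    def cbam_reduction(self) -> int:
        return _VARIANTS[self.variant]["cbam_reduction"]

    @property
    def final_channels(self) -> int:
        return self.stage_channels[-1]


@dataclass(frozen=True)
class TrainConfig:
    stage1_epochs: int = 30
    stage2_epochs: int = 30
    lr_head_stage1: float = 1e-3
    lr_backbone_stage2: float = 1e-5
    lr_head_stage2: float = 1e-4
    weight_decay: float = 1e-4
    batch_size: int = 16
    betas: tuple = (0.9, 0.999)
    dropout_p: float = 0.5
    split: tuple = (0.70, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split must sum to 1, got {self.split}")
        for r in (self.lr_head_stage1, self.lr_backbone_stage2, self.lr_head_stage2):
            if r <= 0:
                raise ValueError("learning rates must be > 0")


class SpermNet(Module):
    """Backbone + per-stage CBAM + GAP⊕GMP head."""

    def __init__(self, cfg: BackboneConfig, n_classes: int, cbam_enabled: bool = True,
                 cbam_reduction: int | None = None, dropout_p: float = 0.5, seed: int = 0):
        super().__init__()
        if n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        self.cfg = cfg
        self.n_classes = n_classes
        self.cbam_enabled = cbam_enabled
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)

        self.stem_conv = Conv2d(3, cfg.stem_channels, 7, stride=2, pad=3, rng=rng)
        self.stem_bn = BatchNorm2d(cfg.stem_channels)

        c_in = cfg.stem_channels
        reduction = cbam_reduction or cfg.cbam_reduction
        self._stage_names: list[list[str]] = []
        self._cbam_names: list[str] = []
        for s, (n_blocks, c_out) in enumerate(zip(cfg.stage_blocks, cfg.stage_channels)):
            names = []
            for b in range(n_blocks):
                stride = 1 if (s == 0 or b > 0) else 2
                name = f"stage{s}_block{b}"
                setattr(self, name, Bottleneck(c_in, c_out, stride, rng=rng))
                names.append(name)
                c_in = c_out
            self._stage_names.append(names)
            if cbam_enabled:
                cname = f"cbam{s}"
                setattr(self, cname, CBAM(c_out, reduction, rng=rng))
                self._cbam_names.append(cname)

        c_final = cfg.final_channels
        self.head_bn = BatchNorm1d(2 * c_final)
        self.head_dropout = Dropout(dropout_p, self._dropout_rng)
        self.head_fc = Linear(2 * c_final, n_classes, rng=rng)
        # near-zero classifier init: initial loss starts at ~ln(n_classes)
        self.head_fc.weight.data *= 0.05

    # ------------------------------------------------------------------ parts
    def backbone_parameters(self):
        out = self.stem_conv.parameters() + self.stem_bn.parameters()
        for names in self._stage_names:
            for name in names:
                out.extend(getattr(self, name).parameters())
        return out

    def head_and_cbam_parameters(self):
        out = self.head_bn.parameters() + self.head_fc.parameters()
        for cname in self._cbam_names:
            out.extend(getattr(self, cname).parameters())
        return out

    def backbone_batchnorms(self):
        for m in [self.stem_bn] + [
            getattr(self, n) for names in self._stage_names for n in names
        ]:
            for sub in m.modules():
                if isinstance(sub, (BatchNorm2d, BatchNorm1d)):
                    yield sub

    # ---------------------------------------------------------------- forward
    def forward(self, x, capture: bool = False):
        """Run the network; with ``capture`` return interior activations too.

        Returns a dict with ``probs`` and ``logits`` (and, when capturing,
        ``conv5`` — the final stage output before CBAM, ``cbam`` — after
        CBAM, ``gap``/``gmp``/``combined``/``prefinal`` head tensors).
        """
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        if t.ndim != 4 or t.shape[1] != 3 or t.shape[2] != self.cfg.input_size:
            raise ValueError(
                f"expected input (N, 3, {self.cfg.input_size}, {self.cfg.input_size}), got {t.shape}"
            )
        out = self.stem_bn(self.stem_conv(t)).relu().maxpool2d(3, 2, 1)
        conv5 = cbam_out = None
        for s, names in enumerate(self._stage_names):
            for name in names:
                out = getattr(self, name)(out)
            if s == len(self._stage_names) - 1:
                conv5 = out
            if self.cbam_enabled:
                out = getattr(self, f"cbam{s}")(out)
        cbam_out = out

        gap = out.mean(axis=(2, 3))
        gmp = out.amax(axis=(2, 3))
        combined = Tensor.concat([gap, gmp], axis=1)
        prefinal = self.head_bn(combined)
        logits = self.head_fc(self.head_dropout(prefinal))
        result = {"logits": logits, "probs": logits.softmax()}
        if capture:
            result.update(conv5=conv5, cbam=cbam_out, gap=gap, gmp=gmp,
                          combined=combined, prefinal=prefinal)
        return result

    def forward_head(self, final_map) -> np.ndarray:
        """Class probabilities from a final refined feature-map batch."""
        f = final_map if isinstance(final_map, Tensor) else Tensor(final_map)
        gap = f.mean(axis=(2, 3))
        gmp = f.amax(axis=(2, 3))
        combined = Tensor.concat([gap, gmp], axis=1)
        logits = self.head_fc(self.head_dropout(self.head_bn(combined)))
        return logits.softmax().data


def build_network(cfg: BackboneConfig, n_classes: int, cbam_cfg: dict | None = None,
                  seed: int = 0) -> SpermNet:
    """Construct a (optionally CBAM-free baseline) network, seeded."""
    cbam_cfg = cbam_cfg or {}
    return SpermNet(
        cfg, n_classes,
        cbam_enabled=cbam_cfg.get("enabled", True),
        cbam_reduction=cbam_cfg.get("reduction"),
        dropout_p=cbam_cfg.get("dropout_p", 0.5),
        seed=seed,
    )


@dataclass
class TrainedNetwork:
    net: SpermNet
    config: BackboneConfig
    train_config: TrainConfig
    class_names: list[str]
    history: dict = field(default_factory=dict)

    def __post_init__(self):
        self.net.eval()


def loss_with_l2(logits: Tensor, labels: np.ndarray, params, weight_decay: float):
    """Cross-entropy graph node plus the scalar L2 penalty value."""
    ce = logits.cross_entropy(labels)
    l2 = weight_decay * float(sum(np.sum(p.data**2) for p in params))
    return ce, ce.data.item() + l2


def stratified_split(y: np.ndarray, fractions, seed: int):
    """Deterministic stratified train/val/test index split."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    parts: list[list[int]] = [[], [], []]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        parts[0].extend(idx[:n_train])
        parts[1].extend(idx[n_train : n_train + n_val])
        parts[2].extend(idx[n_train + n_val :])
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)


def _run_epoch(net: SpermNet, x, y, order, batch_size, optimizer, weight_decay):
    losses, correct = [], 0
    params = [p for group, _ in optimizer.groups for p in group]
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        out = net.forward(x[idx])
        ce, total = loss_with_l2(out["logits"], y[idx], params, weight_decay)
        optimizer.zero_grad()
        ce.backward()
        optimizer.step()
        losses.append(total)
        correct += int((out["probs"].data.argmax(axis=1) == y[idx]).sum())
    return float(np.mean(losses)), correct / len(order)


def _eval_accuracy(net: SpermNet, x, y, batch_size=32):
    was_training = net.training
    net.eval()
    preds = []
    for start in range(0, len(x), batch_size):
        preds.append(net.forward(x[start : start + batch_size])["probs"].data.argmax(axis=1))
    net.train(was_training)
    return float(np.mean(np.concatenate(preds) == y)) if len(x) else float("nan")


def train_two_stage(net: SpermNet, x: np.ndarray, y: np.ndarray, class_names,
                    cfg: TrainConfig, x_val=None, y_val=None) -> TrainedNetwork:
    """Stage 1: frozen backbone, CBAM+head at lr_head_stage1.
    Stage 2: full fine-tune at (lr_backbone_stage2, lr_head_stage2).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    if len(x) == 0:
        raise ValueError("empty training set")
    if y.max() >= net.n_classes:
        raise ValueError(f"label {y.max()} out of range for {net.n_classes} classes")
    rng = np.random.default_rng(cfg.seed)
    history = {"stage1": [], "stage2": []}

    def epochs(stage, optimizer, n_epochs):
        for _ in range(n_epochs):
            order = rng.permutation(len(x))
            loss, acc = _run_epoch(net, x, y, order, cfg.batch_size, optimizer, cfg.weight_decay)
            rec = {"loss": loss, "train_acc": acc}
            if x_val is not None and len(x_val):
                rec["val_acc"] = _eval_accuracy(net, x_val, y_val)
            history[stage].append(rec)

    # Stage 1: backbone parameters are excluded from the optimizer, so they
    # are bit-identical before and after; batch-norm layers keep tracking
    # running statistics (the usual frozen-backbone convention).
    net.train()
    opt1 = Adam([(net.head_and_cbam_parameters(), cfg.lr_head_stage1)],
                betas=cfg.betas, weight_decay=cfg.weight_decay)
    epochs("stage1", opt1, cfg.stage1_epochs)

    opt2 = Adam([
        (net.backbone_parameters(), cfg.lr_backbone_stage2),
        (net.head_and_cbam_parameters(), cfg.lr_head_stage2),
    ], betas=cfg.betas, weight_decay=cfg.weight_decay)
    epochs("stage2", opt2, cfg.stage2_epochs)

    return TrainedNetwork(net=net, config=net.cfg, train_config=cfg,
                          class_names=list(class_names), history=history)


def predict(trained: TrainedNetwork, x: np.ndarray, batch_size: int = 32):
    """Argmax labels (ties -> lowest class index) and probabilities, eval mode."""
    net = trained.net
    net.eval()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4 or x.shape[2] != net.cfg.input_size:
        raise ValueError(
            f"expected (N, 3, {net.cfg.input_size}, {net.cfg.input_size}), got {x.shape}"
        )
    probs = np.concatenate([
        net.forward(x[s : s + batch_size])["probs"].data for s in range(0, len(x), batch_size)
    ])
    return probs.argmax(axis=1), probs


def save_checkpoint(trained: TrainedNetwork, path):
    """Weight archive (.npz) plus a JSON sidecar with config and history."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path.with_suffix(".npz"), **trained.net.state_arrays())
    sidecar = {
        "backbone": asdict(trained.config),
        "train": asdict(trained.train_config),
        "class_names": trained.class_names,
        "history": trained.history,
        "n_classes": trained.net.n_classes,
        "cbam_enabled": trained.net.cbam_enabled,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path) -> TrainedNetwork:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    bcfg = BackboneConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                             for k, v in sidecar["backbone"].items()})
    tcfg = TrainConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                          for k, v in sidecar["train"].items()})
    net = SpermNet(bcfg, sidecar["n_classes"], cbam_enabled=sidecar["cbam_enabled"])
    with np.load(path.with_suffix(".npz")) as arrays:
        net.load_state_arrays({k: arrays[k] for k in arrays.files})
    return TrainedNetwork(net=net, config=bcfg, train_config=tcfg,
                          class_names=sidecar["class_names"], history=sidecar["history"])
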