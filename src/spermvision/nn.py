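"""Layer library: convolution, batch norm, linear, dropout, CBAM blocks.

Initialization follows Kaiming-uniform fan-in scaling and is fully seeded:
every module draws its weights from the ``rng`` handed to it, so a network
built twice from the same seed is bit-identical.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor

__all__ = [
    "Module", "Conv2d", "BatchNorm2d", "BatchNorm1d", "Linear", "Dropout",
    "ChannelAttention", "SpatialAttention", "CBAM", "Bottleneck",
]


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Base class: tracks child modules and parameters, train/eval mode."""

    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Parameter] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        elif isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Parameter]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        """Flat name -> array map of parameters and buffers (for checkpoints)."""
        out = {}
        for name, p in self._params.items():
            out[prefix + name] = p.data
        for name, buf in getattr(self, "_buffers", {}).items():
            out[prefix + name] = buf
        for name, m in self._modules.items():
            out.update(m.state_arrays(prefix + name + "."))
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray], prefix: str = ""):
        for name, p in self._params.items():
            p.data = np.array(arrays[prefix + name], dtype=np.float64)
        for name in getattr(self, "_buffers", {}):
            self._buffers[name] = np.array(arrays[prefix + name], dtype=np.float64)
        for name, m in self._modules.items():
            m.load_state_arrays(arrays, prefix + name + ".")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, c_in, c_out, kernel, stride=1, pad=0, bias=False, *, rng):
        super().__init__()
        self.stride, self.pad = stride, pad
        fan_in = c_in * kernel * kernel
        self.weight = Parameter(kaiming_uniform(rng, (c_out, c_in, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(c_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, pad=self.pad)


class _BatchNorm(Module):
    # momentum 0.3: running estimates converge within the short training
    # schedules used at desk scale, keeping inference-mode behavior close
    # to training-mode behavior after a few dozen batches.
    def __init__(self, num_features: int, momentum: float = 0.3, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.momentum, self.eps = momentum, eps
        self._buffers = {
            "running_mean": np.zeros(num_features),
            "running_var": np.ones(num_features),
        }
        self.frozen_stats = False  # inference statistics even in train mode

    def _normalize(self, x: Tensor, axes: tuple, shape) -> Tensor:
        if self.training and not self.frozen_stats:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=axes, keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] *= 1 - m
            self._buffers["running_mean"] += m * mu.data.reshape(-1)
            self._buffers["running_var"] *= 1 - m
            self._buffers["running_var"] += m * var.data.reshape(-1)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
        return (x - mu) / (var + self.eps).sqrt()


class BatchNorm2d(_BatchNorm):
    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        xhat = self._normalize(x, (0, 2, 3), (1, c, 1, 1))
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class BatchNorm1d(_BatchNorm):
    def forward(self, x: Tensor) -> Tensor:
        d = x.shape[1]
        xhat = self._normalize(x, (0,), (1, d))
        return xhat * self.gamma.reshape(1, d) + self.beta.reshape(1, d)


class Linear(Module):
    def __init__(self, d_in, d_out, bias=True, *, rng):
        super().__init__()
        self.weight = Parameter(kaiming_uniform(rng, (d_in, d_out), d_in))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        return out + self.bias.reshape(1, -1) if self.bias is not None else out


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        keep = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(keep)


class ChannelAttention(Module):
    """Sigmoid channel mask from GAP/GMP descriptors through a shared MLP.

    The MLP (one hidden ReLU layer, no biases) is shared between the two
    pooled descriptors and its outputs are summed before the sigmoid.

    The output layer starts at zero so the mask begins exactly neutral
    (0.5 everywhere) and attention is learned rather than imposed — the
    same convention as zero-initializing the last norm layer of a
    residual branch.
    """

    def __init__(self, channels: int, reduction: int, *, rng):
        super().__init__()
        if channels % reduction:
            raise ValueError(f"channels {channels} not divisible by reduction {reduction}")
        hidden = channels // reduction
        self.w1 = Parameter(kaiming_uniform(rng, (channels, hidden), channels))
        self.w2 = Parameter(np.zeros((hidden, channels)))

    def _mlp(self, x: Tensor) -> Tensor:
        return (x @ self.w1).relu() @ self.w2

    def forward(self, f: Tensor) -> Tensor:
        gap = f.mean(axis=(2, 3))          # (N, C)
        gmp = f.amax(axis=(2, 3))
        return (self._mlp(gap) + self._mlp(gmp)).sigmoid()


class SpatialAttention(Module):
    """Sigmoid spatial mask from channel-mean/max planes through a 7x7 conv.

    Starts neutral: zero kernel and bias give a 0.5 mask everywhere.
    """

    def __init__(self, *, rng):
        super().__init__()
        self.conv = Conv2d(2, 1, 7, stride=1, pad=3, bias=True, rng=rng)
        self.conv.weight.data[:] = 0.0

    def forward(self, f: Tensor) -> Tensor:
        avg = f.mean(axis=1, keepdims=True)       # (N,1,H,W)
        mx = f.amax(axis=1, keepdims=True)
        pooled = Tensor.concat([avg, mx], axis=1)  # [Avg; Max] order
        return self.conv(pooled).sigmoid()


class CBAM(Module):
    """Sequential channel-then-spatial attention refinement."""

    def __init__(self, channels: int, reduction: int, *, rng):
        super().__init__()
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(rng=rng)

    def forward(self, f: Tensor) -> Tensor:
        n, c = f.shape[0], f.shape[1]
        mc = self.channel(f).reshape(n, c, 1, 1)
        fp = f * mc
        ms = self.spatial(fp)                      # (N,1,H,W)
        return fp * ms


class Bottleneck(Module):
    """1x1 reduce -> 3x3 -> 1x1 expand, each BN+ReLU, plus shortcut."""

    def __init__(self, c_in, c_out, stride, *, rng):
        super().__init__()
        width = c_out // 4
        self.conv1 = Conv2d(c_in, width, 1, rng=rng)
        self.bn1 = BatchNorm2d(width)
        self.conv2 = Conv2d(width, width, 3, stride=stride, pad=1, rng=rng)
        self.bn2 = BatchNorm2d(width)
        self.conv3 = Conv2d(width, c_out, 1, rng=rng)
        self.bn3 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj = Conv2d(c_in, c_out, 1, stride=stride, rng=rng)
            self.proj_bn = BatchNorm2d(c_out)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        shortcut = self.proj_bn(self.proj(x)) if self.proj is not None else x
        return (out + shortcut).relu()
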