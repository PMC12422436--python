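"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The engine provides exactly the operations a small attention-augmented
residual classifier needs: broadcasting arithmetic, matrix products,
strided 2-D convolution and max-pooling, ReLU/sigmoid, axis reductions,
reshape/concat, and a fused softmax cross-entropy.  Tensors form a DAG;
``Tensor.backward`` runs a topological sweep and accumulates gradients
on every node, which is what Grad-CAM needs (gradients at interior
activations, not just leaves).

Float64 is the working dtype throughout: the networks trained here are
desk-scale, and exact-ish arithmetic keeps oracle comparisons tight.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _node(data, parents, backward):
        out = Tensor(data)
        live = [p for p in parents if isinstance(p, Tensor)]
        out.requires_grad = any(p.requires_grad for p in live) or bool(live)
        out._parents = tuple(live)
        out._backward = backward
        return out

    def backward(self, grad=None):
        """Backpropagate from this tensor; seeds with ``grad`` (default ones)."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------- arithmetic
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def __add__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.shape))
            other._accum(_unbroadcast(g, other.shape))

        return Tensor._node(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return Tensor._node(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.shape))
            other._accum(_unbroadcast(g * self.data, other.shape))

        return Tensor._node(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.shape))
            other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return Tensor._node(self.data / other.data, (self, other), backward)

    def pow(self, exponent: float):
        def backward(g):
            self._accum(g * exponent * self.data ** (exponent - 1))

        return Tensor._node(self.data**exponent, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accum(g * 0.5 / np.maximum(out_data, 1e-300))

        return Tensor._node(out_data, (self,), backward)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = Tensor._lift(other)

        def backward(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        return Tensor._node(self.data @ other.data, (self, other), backward)

    __matmul__ = matmul

    # ------------------------------------------------------------ activations
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return Tensor._node(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return Tensor._node(out_data, (self,), backward)

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape):
        old = self.shape

        def backward(g):
            self._accum(g.reshape(old))

        return Tensor._node(self.data.reshape(*shape), (self,), backward)

    @staticmethod
    def concat(tensors, axis: int):
        tensors = [Tensor._lift(t) for t in tensors]
        sizes = [t.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)

        def backward(g):
            for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

        return Tensor._node(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)

    # -------------------------------------------------------------- reductions
    def mean(self, axis=None, keepdims: bool = False):
        axis_t = axis if axis is None else (axis if isinstance(axis, tuple) else (axis,))
        count = self.data.size if axis is None else int(np.prod([self.shape[a] for a in axis_t]))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis_t)
            self._accum(np.broadcast_to(g, self.shape) / count)

        return Tensor._node(self.data.mean(axis=axis, keepdims=keepdims), (self,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        axis_t = axis if axis is None else (axis if isinstance(axis, tuple) else (axis,))

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis_t)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def amax(self, axis, keepdims: bool = False):
        """Maximum over ``axis``; gradient split equally among ties."""
        axis_t = axis if isinstance(axis, tuple) else (axis,)
        out_data = self.data.max(axis=axis_t, keepdims=True)
        mask = (self.data == out_data).astype(np.float64)
        mask /= mask.sum(axis=axis_t, keepdims=True)

        def backward(g):
            if not keepdims:
                g = np.expand_dims(g, axis_t)
            self._accum(mask * g)

        res = out_data if keepdims else out_data.squeeze(axis=axis_t)
        return Tensor._node(res, (self,), backward)

    # ------------------------------------------------------------ convolution
    @staticmethod
    def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, pad_value: float = 0.0):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=pad_value)
        ho = (h + 2 * pad - kh) // stride + 1
        wo = (w + 2 * pad - kw) // stride + 1
        s0, s1, s2, s3 = xp.strides
        view = np.lib.stride_tricks.as_strided(
            xp,
            shape=(n, c, ho, wo, kh, kw),
            strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
            writeable=False,
        )
        return view, ho, wo

    def conv2d(self, weight: "Tensor", bias: "Tensor | None", stride: int = 1, pad: int = 0):
        """2-D cross-correlation, zero padding.

        ``self``: (N, C, H, W); ``weight``: (O, C, kh, kw); ``bias``: (O,) or None.
        """
        n, c, h, w = self.shape
        o, c2, kh, kw = weight.shape
        if c != c2:
            raise ValueError(f"conv2d channel mismatch: input has {c}, kernel expects {c2}")
        view, ho, wo = Tensor._im2col(self.data, kh, kw, stride, pad)
        cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
        wmat = weight.data.reshape(o, c * kh * kw).T
        out = (cols @ wmat).reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
        if bias is not None:
            out = out + bias.data[None, :, None, None]
        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g):
            gmat = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
            weight._accum((gmat.T @ cols).reshape(o, c, kh, kw))
            if bias is not None:
                bias._accum(g.sum(axis=(0, 2, 3)))
            dcols = (gmat @ wmat.T).reshape(n, ho, wo, c, kh, kw)
            dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + ho * stride : stride, j : j + wo * stride : stride] += (
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                    )
            self._accum(dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp)

        return Tensor._node(out, parents, backward)

    def maxpool2d(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        n, c, h, w = self.shape
        view, ho, wo = Tensor._im2col(self.data, kernel, kernel, stride, pad, pad_value=-np.inf)
        patches = view.reshape(n, c, ho, wo, kernel * kernel)
        arg = patches.argmax(axis=-1)
        out = np.take_along_axis(patches, arg[..., None], axis=-1)[..., 0]

        def backward(g):
            dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
            ki, kj = np.divmod(arg, kernel)
            oi, oj = np.meshgrid(np.arange(ho), np.arange(wo), indexing="ij")
            rows = oi[None, None] * stride + ki
            colx = oj[None, None] * stride + kj
            ni = np.arange(n)[:, None, None, None]
            ci = np.arange(c)[None, :, None, None]
            np.add.at(dxp, (ni, ci, rows, colx), g)
            self._accum(dxp[:, :, pad : pad + h, pad : pad + w] if pad else dxp)

        return Tensor._node(out, (self,), backward)

    # ------------------------------------------------------------------- loss
    def log_softmax(self):
        z = self.data - self.data.max(axis=1, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
        out_data = z - lse

        def backward(g):
            p = np.exp(out_data)
            self._accum(g - p * g.sum(axis=1, keepdims=True))

        return Tensor._node(out_data, (self,), backward)

    def softmax(self):
        z = self.data - self.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        out_data = e / e.sum(axis=1, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=1, keepdims=True)
            self._accum(out_data * (g - dot))

        return Tensor._node(out_data, (self,), backward)

    def cross_entropy(self, labels: np.ndarray) -> "Tensor":
        """Mean negative log-likelihood of integer ``labels`` under softmax(self)."""
        labels = np.asarray(labels)
        n = self.shape[0]
        logp = self.log_softmax()
        picked = Tensor._node(
            logp.data[np.arange(n), labels],
            (logp,),
            lambda g: logp._accum(_scatter_rows(g, labels, logp.shape)),
        )
        return -(picked.mean())


def _scatter_rows(g, labels, shape):
    out = np.zeros(shape)
    out[np.arange(shape[0]), labels] = g
    return out


class Parameter(Tensor):
    """A leaf tensor updated by an optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Adam:
    """Adam with per-group learning rates and decoupled-from-graph L2 term.

    The L2 penalty lambda * ||theta||^2 contributes 2*lambda*theta to each
    gradient; it is added here rather than through the graph so the loss
    graph stays small.
    """

    def __init__(self, groups, betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.0):
        # groups: list of (params, lr)
        self.groups = [(list(ps), float(lr)) for ps, lr in groups]
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.state = {}
        for ps, _ in self.groups:
            for p in ps:
                self.state[id(p)] = (np.zeros_like(p.data), np.zeros_like(p.data))

    def zero_grad(self):
        for ps, _ in self.groups:
            for p in ps:
                p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for ps, lr in self.groups:
            for p in ps:
                g = p.grad if p.grad is not None else np.zeros_like(p.data)
                if self.weight_decay:
                    g = g + 2.0 * self.weight_decay * p.data
                m, v = self.state[id(p)]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * g * g
                p.data -= lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
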