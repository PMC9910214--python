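"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the numerical substrate for the slice network, the 2D backbone,
the attention blocks and the classifier head: a small tape-based autograd
engine (:class:`Tensor`), layer modules built on it, and an Adam optimizer.
Everything runs in float64 on the CPU; the problem sizes this package
targets (tens of small phantom volumes, a handful of conv stages) do not
need more.

Multiply-add (MAD) accounting is wired into the compute-bearing primitives
(``conv2d``, ``linear``-style matmuls): inside a :func:`count_mads` context
every convolution adds ``k_h*k_w*C_in*C_out*H_out*W_out`` and every matmul
adds its inner-product volume, so an instrumented forward pass yields the
analytic per-pass count.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "DTYPE",
    "set_default_dtype",
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "Conv1dChannel",
    "Linear",
    "BatchNorm1d",
    "BatchNorm2d",
    "Dropout",
    "ReLU",
    "Sequential",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "Adam",
    "conv2d",
    "maxpool2d",
    "softmax",
    "log_softmax",
    "kaiming_normal",
    "mad_counter",
]


# ---------------------------------------------------------------------------
# default dtype
# ---------------------------------------------------------------------------

#: engine-wide float type. float32 keeps CPU training fast; switch to float64
#: (set_default_dtype) when checking gradients against finite differences.
DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    global DTYPE
    if dtype not in (np.float32, np.float64):
        raise ValueError("dtype must be np.float32 or np.float64")
    DTYPE = dtype


# ---------------------------------------------------------------------------
# MAD accounting
# ---------------------------------------------------------------------------

_MAD_STACK: list[list[int]] = []


@contextlib.contextmanager
def mad_counter():
    """Context manager accumulating multiply-add counts of ops run inside it.

    Yields a one-element list; after the block, ``counter[0]`` holds the total.
    """
    acc = [0]
    _MAD_STACK.append(acc)
    try:
        yield acc
    finally:
        _MAD_STACK.pop()


def _record_mads(n: int) -> None:
    for acc in _MAD_STACK:
        acc[0] += int(n)


# ---------------------------------------------------------------------------
# Tensor
# ---------------------------------------------------------------------------


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward: Callable[[], None] | None = None
        self._prev = _prev

    # -- bookkeeping --------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            # copy: g may alias a downstream grad buffer that is still in use
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order over the tape
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- arithmetic ---------------------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _back():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = _back
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _back():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = _back
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return self._wrap(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        out = Tensor(np.power(self.data, exponent), _prev=(self,))

        def _back():
            if self.requires_grad:
                self._accumulate(out.grad * exponent * np.power(self.data, exponent - 1.0))

        out._backward = _back
        return out

    def sqrt(self):
        return self.pow(0.5)

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(np.matmul(self.data, other.data), _prev=(self, other))
        # inner-product volume = output elements * shared dimension
        _record_mads(out.data.size * self.data.shape[-1])

        def _back():
            g = out.grad
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accumulate(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accumulate(_unbroadcast(gb, other.data.shape))

        out._backward = _back
        return out

    # -- elementwise nonlinearities -----------------------------------------

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _back():
            if self.requires_grad:
                self._accumulate(out.grad * (self.data > 0))

        out._backward = _back
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, _prev=(self,))

        def _back():
            if self.requires_grad:
                self._accumulate(out.grad * s * (1.0 - s))

        out._backward = _back
        return out

    def exp(self):
        e = np.exp(self.data)
        out = Tensor(e, _prev=(self,))

        def _back():
            if self.requires_grad:
                self._accumulate(out.grad * e)

        out._backward = _back
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _back():
            if self.requires_grad:
                self._accumulate(out.grad / self.data)

        out._backward = _back
        return out

    # -- shape ops ----------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def _back():
            if self.requires_grad:
                self._accumulate(out.grad.reshape(old))

        out._backward = _back
        return out

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), _prev=(self,))

        def _back():
            if self.requires_grad:
                self._accumulate(out.grad.transpose(inv))

        out._backward = _back
        return out

    # -- reductions ---------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))
        shape = self.data.shape

        def _back():
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, shape).copy())

        out._backward = _back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        """Maximum along one axis; ties split gradient equally."""
        m = self.data.max(axis=axis, keepdims=True)
        out = Tensor(m if keepdims else np.squeeze(m, axis=axis), _prev=(self,))
        mask = (self.data == m).astype(self.data.dtype)
        mask /= mask.sum(axis=axis, keepdims=True)

        def _back():
            if not self.requires_grad:
                return
            g = out.grad if keepdims else np.expand_dims(out.grad, axis)
            self._accumulate(mask * g)

        out._backward = _back
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (max-subtracted before exponentiation)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))  # constant; softmax is shift-invariant
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    z = x - shift
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2D convolution (cross-correlation) via im2col.

    x: (B, C_in, H, W); weight: (C_out, C_in, kH, kW); bias: (C_out,) or None.
    """
    B, C, H, W = x.data.shape
    Co, Ci, kh, kw = weight.data.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, kernel expects {Ci}")
    if padding:
        xp = np.zeros((B, C, H + 2 * padding, W + 2 * padding), dtype=x.data.dtype)
        xp[:, :, padding:-padding, padding:-padding] = x.data
    else:
        xp = x.data
    Ho = (H + 2 * padding - kh) // stride + 1
    Wo = (W + 2 * padding - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]          # B, C, Ho, Wo, kh, kw
    col = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * Ho * Wo, C * kh * kw)
    wmat = weight.data.reshape(Co, C * kh * kw)
    out_data = col @ wmat.T
    if bias is not None:
        out_data = out_data + bias.data
    out_data = out_data.reshape(B, Ho, Wo, Co).transpose(0, 3, 1, 2)
    _record_mads(kh * kw * C * Co * Ho * Wo * B)

    prev = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor(out_data, _prev=prev)

    def _back():
        g = out.grad.transpose(0, 2, 3, 1).reshape(B * Ho * Wo, Co)
        if weight.requires_grad:
            weight._accumulate((g.T @ col).reshape(Co, C, kh, kw))
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=0))
        if x.requires_grad:
            dcol = (g @ wmat).reshape(B, Ho, Wo, C, kh, kw).transpose(0, 3, 4, 5, 1, 2)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + stride * Ho:stride, j:j + stride * Wo:stride] += dcol[:, :, i, j]
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    out._backward = _back
    return out


def maxpool2d(x: Tensor, kernel: int, stride: int, padding: int = 0) -> Tensor:
    """Max pooling; padded positions are -inf and never win."""
    B, C, H, W = x.data.shape
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    Ho = (xp.shape[2] - kernel) // stride + 1
    Wo = (xp.shape[3] - kernel) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # B,C,Ho,Wo,k,k
    flat = win.reshape(B, C, Ho, Wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0], _prev=(x,))

    def _back():
        if not x.requires_grad:
            return
        dxp = np.zeros_like(xp)
        ki, kj = np.unravel_index(arg, (kernel, kernel))
        b, c, io, jo = np.meshgrid(np.arange(B), np.arange(C), np.arange(Ho),
                                   np.arange(Wo), indexing="ij")
        np.add.at(dxp, (b, c, io * stride + ki, jo * stride + kj), out.grad)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)

    out._backward = _back
    return out


def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int) -> np.ndarray:
    """He initialization: N(0, sqrt(2/fan_in)) — suited to ReLU stacks."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------


class Module:
    """Base class: parameter discovery and train/eval mode propagation."""

    def __init__(self):
        self.training = True

    def _children(self) -> Iterable["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Parameter):
                        params.append(item)
                    elif isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def train(self) -> "Module":
        self.training = True
        for c in self._children():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for c in self._children():
            c.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # checkpoint plumbing -----------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        """All parameters plus running statistics, in a stable order."""
        arrays = [p.data for p in self.parameters()]
        for m in self._modules_recursive():
            if isinstance(m, (BatchNorm1d, BatchNorm2d)):
                arrays.extend([m.running_mean, m.running_var])
        return arrays

    def load_state_arrays(self, arrays: Sequence[np.ndarray]) -> None:
        arrays = list(arrays)
        params = self.parameters()
        for p, a in zip(params, arrays[: len(params)]):
            if p.data.shape != a.shape:
                raise ValueError("checkpoint shape mismatch")
            p.data = np.asarray(a, dtype=DTYPE)
        rest = arrays[len(params):]
        i = 0
        for m in self._modules_recursive():
            if isinstance(m, (BatchNorm1d, BatchNorm2d)):
                m.running_mean = np.asarray(rest[i], dtype=DTYPE)
                m.running_var = np.asarray(rest[i + 1], dtype=DTYPE)
                i += 2

    def _modules_recursive(self) -> Iterable["Module"]:
        yield self
        for c in self._children():
            yield from c._modules_recursive()


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, bias: bool = True, *, rng: np.random.Generator):
        super().__init__()
        if in_ch < 1 or out_ch < 1:
            raise ValueError("channel widths must be positive")
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(kaiming_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class Conv1dChannel(Module):
    """1D convolution across the channel axis of a (B, C) descriptor.

    Zero-padded, single filter, no bias — the cost-efficient channel-attention
    convolution (ECA-style)."""

    def __init__(self, kernel: int, *, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0 or kernel < 1:
            raise ValueError("channel-attention kernel size must be odd and >= 1")
        self.kernel = kernel
        self.weight = Parameter(kaiming_normal(rng, (kernel,), kernel))

    def forward(self, x: Tensor) -> Tensor:
        B, C = x.data.shape
        k, half = self.kernel, self.kernel // 2
        xp = np.pad(x.data, ((0, 0), (half, half)))
        win = np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # B,C,k
        out_data = win @ self.weight.data
        _record_mads(B * C * k)
        out = Tensor(out_data, _prev=(x, self.weight))
        weight = self.weight

        def _back():
            g = out.grad
            if weight.requires_grad:
                weight._accumulate(np.einsum("bc,bck->k", g, win))
            if x.requires_grad:
                gp = np.zeros_like(xp)
                for j in range(k):
                    gp[:, j:j + C] += g * weight.data[j]
                x._accumulate(gp[:, half:half + C])

        out._backward = _back
        return out


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, *, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_features, out_features))
        else:
            w = kaiming_normal(rng, (in_features, out_features), in_features)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = xc * (var + self.eps).pow(-0.5)
        else:
            xhat = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones((1, num_features, 1, 1)))
        self.beta = Parameter(np.zeros((1, num_features, 1, 1)))
        self.running_mean = np.zeros((1, num_features, 1, 1))
        self.running_var = np.ones((1, num_features, 1, 1))
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data
            xhat = xc * (var + self.eps).pow(-0.5)
        else:
            xhat = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode. Mask draws come from ``rng``."""

    def __init__(self, p: float, *, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return maxpool2d(x, self.kernel, self.stride, self.padding)


class GlobalAvgPool2d(Module):
    """(B, C, H, W) -> (B, C) spatial mean."""

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: Sequence[Parameter], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
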