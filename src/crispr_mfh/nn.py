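"""A compact reverse-mode automatic-differentiation core over NumPy arrays.

Everything the off-target network needs — dense layers, 2-D and depthwise
convolutions with same-padding, batch normalization, global/channel-wise
pooling, dropout, sigmoid/ReLU, and a fused softmax cross-entropy — is
implemented here as differentiable operations on :class:`Tensor` plus a
handful of layer classes and an Adam optimizer. Feature maps follow the
NHWC layout (batch, height=sequence position, width=channel grid, channels).

The engine is deliberately small: stride-1 same-padded convolutions only,
which is all a 23 x 7 input grid calls for. Convolutions are evaluated as a
sum over kernel offsets of batched matrix products, which keeps both the
forward and the adjoint passes vectorized.
"""

from __future__ import annotations

import numpy as np

try:  # fused depthwise kernels; NumPy fallback below keeps results identical
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a standard install here
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap


@njit(fastmath=True, cache=True)
def _depthwise_forward(xp, w, out):  # pragma: no cover - exercised via wrapper
    n, h, wd, c = out.shape
    kh, kw = w.shape[0], w.shape[1]
    for b in range(n):
        for i in range(kh):
            for j in range(kw):
                for y in range(h):
                    for x in range(wd):
                        for ch in range(c):
                            out[b, y, x, ch] += xp[b, y + i, x + j, ch] * w[i, j, ch]


@njit(fastmath=True, cache=True)
def _depthwise_backward(xp, w, g, dxp, dw):  # pragma: no cover
    n, h, wd, c = g.shape
    kh, kw = w.shape[0], w.shape[1]
    for b in range(n):
        for i in range(kh):
            for j in range(kw):
                for y in range(h):
                    for x in range(wd):
                        for ch in range(c):
                            gv = g[b, y, x, ch]
                            dxp[b, y + i, x + j, ch] += gv * w[i, j, ch]
                            dw[i, j, ch] += gv * xp[b, y + i, x + j, ch]


# ---------------------------------------------------------------------------
# Tensor and autodiff graph
# ---------------------------------------------------------------------------


class Tensor:
    """An ndarray with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def _accumulate(self, grad):
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- operator sugar -----------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), _as_tensor(-1.0)))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_graph(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in tensors)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _needs_graph(*parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# Elementwise / linear-algebra primitives
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    data = a.data + b.data

    def backward(grad):
        a._accumulate(_unbroadcast(grad, a.shape))
        b._accumulate(_unbroadcast(grad, b.shape))

    return _make(data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data * b.data

    def backward(grad):
        a._accumulate(_unbroadcast(grad * b.data, a.shape))
        b._accumulate(_unbroadcast(grad * a.data, b.shape))

    return _make(data, (a, b), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    data = a.data @ b.data

    def backward(grad):
        a._accumulate(_unbroadcast(grad @ np.swapaxes(b.data, -1, -2), a.shape))
        b._accumulate(_unbroadcast(np.swapaxes(a.data, -1, -2) @ grad, b.shape))

    return _make(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    data = x.data * mask

    def backward(grad):
        x._accumulate(grad * mask)

    return _make(data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    data = 1.0 / (1.0 + np.exp(-x.data))

    def backward(grad):
        x._accumulate(grad * data * (1.0 - data))

    return _make(data, (x,), backward)


def sqrt(x: Tensor) -> Tensor:
    data = np.sqrt(x.data)

    def backward(grad):
        x._accumulate(grad * 0.5 / data)

    return _make(data, (x,), backward)


def reciprocal(x: Tensor) -> Tensor:
    data = 1.0 / x.data

    def backward(grad):
        x._accumulate(-grad * data * data)

    return _make(data, (x,), backward)


def reshape(x: Tensor, shape) -> Tensor:
    data = x.data.reshape(shape)

    def backward(grad):
        x._accumulate(grad.reshape(x.shape))

    return _make(data, (x,), backward)


def mean(x: Tensor, axis, keepdims: bool = False) -> Tensor:
    axis = tuple(axis) if isinstance(axis, (list, tuple)) else (axis,)
    data = x.data.mean(axis=axis, keepdims=keepdims)
    count = np.prod([x.shape[a] for a in axis])

    def backward(grad):
        g = grad
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(np.broadcast_to(g, x.shape) / count)

    return _make(data, (x,), backward)


def amax(x: Tensor, axis, keepdims: bool = False) -> Tensor:
    """Max over axes; ties share the gradient equally."""
    axis = tuple(axis) if isinstance(axis, (list, tuple)) else (axis,)
    kept = x.data.max(axis=axis, keepdims=True)
    data = kept if keepdims else np.squeeze(kept, axis=axis)
    mask = (x.data == kept).astype(np.float32)
    mask /= mask.sum(axis=axis, keepdims=True)

    def backward(grad):
        g = grad
        if not keepdims:
            g = np.expand_dims(g, axis)
        x._accumulate(mask * g)

    return _make(data, (x,), backward)


def concatenate(tensors, axis: int) -> Tensor:
    tensors = list(tensors)
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            index = [slice(None)] * grad.ndim
            index[axis] = slice(lo, hi)
            t._accumulate(grad[tuple(index)])

    return _make(data, tensors, backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate is 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate).astype(np.float32) / (1.0 - rate)

    def backward(grad):
        x._accumulate(grad * mask)

    return _make(x.data * mask, (x,), backward)


# ---------------------------------------------------------------------------
# Convolutions (NHWC, stride 1, same padding)
# ---------------------------------------------------------------------------


def _pad_same(data: np.ndarray, kh: int, kw: int) -> tuple[np.ndarray, int, int]:
    ph, pw = kh // 2, kw // 2
    padded = np.pad(data, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    return padded, ph, pw


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 2-D convolution.

    ``x``: (N, H, W, Cin); ``weight``: (kh, kw, Cin, Cout); ``bias``: (Cout,).
    """
    kh, kw, cin, cout = weight.shape
    n, h, w, _ = x.shape
    xp, ph, pw = _pad_same(x.data, kh, kw)
    out = np.zeros((n, h, w, cout), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            out += np.tensordot(xp[:, i:i + h, j:j + w, :], weight.data[i, j],
                                axes=([3], [0]))
    if bias is not None:
        out += bias.data

    def backward(grad):
        if weight.requires_grad or weight._parents:
            dw = np.empty_like(weight.data)
            for i in range(kh):
                for j in range(kw):
                    dw[i, j] = np.tensordot(xp[:, i:i + h, j:j + w, :], grad,
                                            axes=([0, 1, 2], [0, 1, 2]))
            weight._accumulate(dw)
        if bias is not None and (bias.requires_grad or bias._parents):
            bias._accumulate(grad.sum(axis=(0, 1, 2)))
        if x.requires_grad or x._parents:
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i:i + h, j:j + w, :] += grad @ weight.data[i, j].T
            x._accumulate(dxp[:, ph:ph + h, pw:pw + w, :])

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(out, parents, backward)


def depthwise_conv2d(x: Tensor, weight: Tensor) -> Tensor:
    """Same-padded stride-1 depthwise convolution (one filter per channel).

    ``x``: (N, H, W, C); ``weight``: (kh, kw, C).
    """
    kh, kw, _ = weight.shape
    n, h, w, c = x.shape
    xp, ph, pw = _pad_same(x.data, kh, kw)
    out = np.zeros((n, h, w, c), dtype=np.float32)
    if _HAVE_NUMBA:
        _depthwise_forward(xp, weight.data, out)
    else:
        for i in range(kh):
            for j in range(kw):
                out += xp[:, i:i + h, j:j + w, :] * weight.data[i, j]

    def backward(grad):
        grad = np.ascontiguousarray(grad, dtype=np.float32)
        dxp = np.zeros_like(xp)
        dw = np.zeros_like(weight.data)
        if _HAVE_NUMBA:
            _depthwise_backward(xp, weight.data, grad, dxp, dw)
        else:
            for i in range(kh):
                for j in range(kw):
                    dw[i, j] = (xp[:, i:i + h, j:j + w, :] * grad).sum(
                        axis=(0, 1, 2))
                    dxp[:, i:i + h, j:j + w, :] += grad * weight.data[i, j]
        if weight.requires_grad or weight._parents:
            weight._accumulate(dw)
        if x.requires_grad or x._parents:
            x._accumulate(dxp[:, ph:ph + h, pw:pw + w, :])

    return _make(out, (x, weight), backward)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------


def softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the last axis (plain ndarray in/out)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    n = logits.shape[0]
    probs = softmax(logits.data)
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()

    def backward(grad):
        g = probs.copy()
        g[np.arange(n), labels] -= 1.0
        logits._accumulate(grad * g / n)

    return _make(np.float32(loss), (logits,), backward)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


class Layer:
    """Base class: a callable with trainable parameters."""

    def parameters(self) -> list[Tensor]:
        params = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Layer):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Layer):
                        params.extend(item.parameters())
        return params


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.weight = Tensor(_he_init(rng, (in_features, out_features), in_features),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.weight), self.bias)


class Conv2d(Layer):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        k = kernel_size
        fan_in = k * k * in_channels
        self.weight = Tensor(_he_init(rng, (k, k, in_channels, out_channels), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32),
                           requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class DepthwiseConv2d(Layer):
    def __init__(self, channels: int, kernel_size: int,
                 rng: np.random.Generator):
        k = kernel_size
        self.weight = Tensor(_he_init(rng, (k, k, channels), k * k),
                             requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return depthwise_conv2d(x, self.weight)


class BatchNorm2d(Layer):
    """Channel-wise batch normalization over (N, H, W).

    Training mode normalizes with batch statistics (differentiably) and
    updates exponential running statistics; inference mode uses the running
    statistics, making the forward pass deterministic.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        if training:
            mu = mean(x, axis=(0, 1, 2), keepdims=True)
            centered = x - mu
            var = mean(mul(centered, centered), axis=(0, 1, 2), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            inv_std = reciprocal(sqrt(add(var, Tensor(self.eps))))
            xhat = mul(centered, inv_std)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = mul(x - Tensor(self.running_mean), Tensor(inv))
        return add(mul(xhat, self.gamma), self.beta)


class Adam:
    """Adaptive-moment gradient descent."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad * p.grad
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
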