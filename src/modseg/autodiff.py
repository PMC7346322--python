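"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operator set the segmentation networks in this package
need: broadcasting arithmetic, matmul, ReLU/sigmoid/exp/log, axis reductions,
softmax, channel concatenation, 3-D convolution (im2col) and 3-D transpose
convolution (the convolution adjoint, computed with the stride-dilation
trick), plus SGD with momentum/weight decay and Kaiming initialisation.

All floating tensors are float32. Convolution layouts follow the common
deep-learning convention: activations ``(N, C, D, H, W)``, convolution
weights ``(C_out, C_in, kd, kh, kw)``, transpose-convolution weights
``(C_in, C_out, kd, kh, kw)``.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != DTYPE:
        a = a.astype(DTYPE)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple["Tensor", ...] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ---- bookkeeping -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        """Reverse-mode sweep from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not (node.requires_grad or node._parents):
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ---- arithmetic ------------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g, self.shape))
            other._accumulate(_unbroadcast(g, other.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g * other.data, self.shape))
            other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bwd(g):
            self._accumulate(_unbroadcast(g / other.data, self.shape))
            other._accumulate(_unbroadcast(-g * self.data / other.data ** 2, other.shape))
        out._backward = bwd
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bwd(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)
        out._backward = bwd
        return out

    # ---- elementwise nonlinearities -------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: self._accumulate(g * s * (1.0 - s))
        return out

    # ---- reductions and shape ops ----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bwd(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).astype(DTYPE))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))
        out._backward = lambda g: self._accumulate(g.reshape(self.shape))
        return out

    def transpose(self, axes: Sequence[int]):
        axes = tuple(axes)
        inv = tuple(np.argsort(axes))
        out = Tensor(self.data.transpose(axes), parents=(self,))
        out._backward = lambda g: self._accumulate(g.transpose(inv))
        return out

    def softmax(self, axis: int):
        """Numerically stable softmax; the max shift carries no gradient
        (softmax is shift invariant)."""
        m = self.data.max(axis=axis, keepdims=True)
        e = (self - Tensor(m)).exp()
        return e / e.sum(axis=axis, keepdims=True)


def concat(tensors: Sequence[Tensor], axis: int) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)
    out._backward = bwd
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.stack([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))

    def bwd(g):
        for t, piece in zip(tensors, np.moveaxis(g, axis, 0)):
            t._accumulate(piece)
    out._backward = bwd
    return out


# --------------------------------------------------------------------------
# Raw 3-D convolution kernels (numpy only)
# --------------------------------------------------------------------------

def _triple(v) -> tuple[int, int, int]:
    if isinstance(v, (tuple, list)):
        if len(v) != 3:
            raise ValueError(f"expected 3 values, got {v!r}")
        return tuple(int(x) for x in v)
    return (int(v),) * 3


def _im2col(x: np.ndarray, ksize, stride, pad) -> tuple[np.ndarray, tuple]:
    """Return (cols, out_spatial); cols has shape (N*Do*Ho*Wo, Ci*kd*kh*kw)."""
    kd, kh, kw = ksize
    sd, sh, sw = stride
    pd, ph, pw = pad
    xp = np.pad(x, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    v = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
    v = v[:, :, ::sd, ::sh, ::sw]
    n, ci, do, ho, wo = v.shape[:5]
    cols = np.ascontiguousarray(v.transpose(0, 2, 3, 4, 1, 5, 6, 7))
    return cols.reshape(n * do * ho * wo, ci * kd * kh * kw), (do, ho, wo)


def conv3d_forward(x: np.ndarray, w: np.ndarray, stride, pad,
                   return_cols: bool = False):
    """x (N,Ci,D,H,W) * w (Co,Ci,kd,kh,kw) -> (N,Co,Do,Ho,Wo)."""
    stride, pad = _triple(stride), _triple(pad)
    n = x.shape[0]
    co = w.shape[0]
    cols, (do, ho, wo) = _im2col(x, w.shape[2:], stride, pad)
    out = cols @ w.reshape(co, -1).T
    out = out.reshape(n, do, ho, wo, co).transpose(0, 4, 1, 2, 3)
    out = np.ascontiguousarray(out)
    return (out, cols) if return_cols else out


def _crop_or_pad(a: np.ndarray, spatial: tuple[int, int, int]) -> np.ndarray:
    """Adjust trailing spatial dims by end-cropping / zero end-padding."""
    slices = [slice(None), slice(None)] + [slice(0, min(a.shape[2 + i], spatial[i]))
                                           for i in range(3)]
    a = a[tuple(slices)]
    pads = [(0, 0), (0, 0)] + [(0, spatial[i] - a.shape[2 + i]) for i in range(3)]
    if any(p[1] for p in pads):
        a = np.pad(a, pads)
    return a


def conv3d_input_grad(dout: np.ndarray, w: np.ndarray, stride, pad,
                      x_spatial: tuple[int, int, int]) -> np.ndarray:
    """Gradient of conv3d_forward w.r.t. its input (also the transpose-conv
    forward map). Computed by stride-dilating `dout` and convolving with the
    spatially flipped, channel-transposed kernel."""
    stride, pad = _triple(stride), _triple(pad)
    n, co, do, ho, wo = dout.shape
    kd, kh, kw = w.shape[2:]
    sd, sh, sw = stride
    dd = np.zeros((n, co, (do - 1) * sd + 1, (ho - 1) * sh + 1, (wo - 1) * sw + 1),
                  dtype=DTYPE)
    dd[:, :, ::sd, ::sh, ::sw] = dout
    wt = np.ascontiguousarray(w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4))
    # Full correlation reconstructs the gradient on the zero-padded input
    # grid; stride remainders leave uncovered tail positions that are zero
    # there, so extend, then strip the convolution padding.
    full = conv3d_forward(dd, wt, (1, 1, 1), (kd - 1, kh - 1, kw - 1))
    padded_spatial = tuple(x_spatial[i] + 2 * pad[i] for i in range(3))
    full = _crop_or_pad(full, padded_spatial)
    return np.ascontiguousarray(
        full[:, :,
             pad[0]:pad[0] + x_spatial[0],
             pad[1]:pad[1] + x_spatial[1],
             pad[2]:pad[2] + x_spatial[2]])


def conv3d_weight_grad(cols: np.ndarray, dout: np.ndarray,
                       w_shape: tuple) -> np.ndarray:
    co = w_shape[0]
    dflat = dout.transpose(0, 2, 3, 4, 1).reshape(-1, co)
    return (dflat.T @ cols).reshape(w_shape)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None, stride, pad) -> Tensor:
    """Differentiable 3-D convolution."""
    stride, pad = _triple(stride), _triple(pad)
    y, cols = conv3d_forward(x.data, w.data, stride, pad, return_cols=True)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)
    x_spatial = x.shape[2:]

    def bwd(g):
        x._accumulate(conv3d_input_grad(g, w.data, stride, pad, x_spatial))
        w._accumulate(conv3d_weight_grad(cols, g, w.data.shape))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
    out._backward = bwd
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None, stride, pad,
                     out_spatial: tuple[int, int, int]) -> Tensor:
    """Differentiable 3-D transpose convolution (adjoint of conv3d).

    ``w`` has shape (C_in, C_out, kd, kh, kw); ``out_spatial`` fixes the
    output size explicitly (the adjoint alone is ambiguous when the forward
    stride did not divide evenly).
    """
    stride, pad = _triple(stride), _triple(pad)
    y = conv3d_input_grad(x.data, w.data, stride, pad, out_spatial)
    if b is not None:
        y = y + b.data.reshape(1, -1, 1, 1, 1)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(y, parents=parents)

    def bwd(g):
        dx, cols_g = conv3d_forward(g, w.data, stride, pad, return_cols=True)
        x._accumulate(_crop_or_pad(dx, x.shape[2:]))
        # d/dw of <adjoint-conv(x, w), g> reuses the conv weight-grad with the
        # roles of input and output gradient swapped.
        dw = conv3d_weight_grad(cols_g, _crop_or_pad(
            np.ascontiguousarray(x.data), dx.shape[2:]), w.data.shape)
        w._accumulate(dw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
    out._backward = bwd
    return out


# --------------------------------------------------------------------------
# Layers
# --------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def kaiming_normal(rng: np.random.Generator, shape: tuple[int, ...],
                   fan_in: int) -> np.ndarray:
    """He initialisation for ReLU-followed layers: N(0, sqrt(2/fan_in))."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Module:
    """Tiny layer base: children and parameters are discovered by attribute
    scan, so sharing a sub-module shares its parameters exactly once."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        self._collect(params, seen)
        return params

    def _collect(self, params: list[Parameter], seen: set[int]):
        for v in self.__dict__.values():
            if isinstance(v, Parameter) and id(v) not in seen:
                seen.add(id(v))
                params.append(v)
            elif isinstance(v, Module):
                v._collect(params, seen)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item._collect(params, seen)
                    elif isinstance(item, Parameter) and id(item) not in seen:
                        seen.add(id(item))
                        params.append(item)

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]


class Linear(Module):
    def __init__(self, rng, in_features: int, out_features: int, bias: bool = True):
        self.weight = Parameter(kaiming_normal(rng, (in_features, out_features),
                                               in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=DTYPE)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        return y if self.bias is None else y + self.bias


class Conv3d(Module):
    def __init__(self, rng, c_in: int, c_out: int, kernel, stride=1, bias=True):
        k = _triple(kernel)
        fan_in = c_in * k[0] * k[1] * k[2]
        self.weight = Parameter(kaiming_normal(rng, (c_out, c_in, *k), fan_in))
        self.bias = Parameter(np.zeros(c_out, dtype=DTYPE)) if bias else None
        self.stride = _triple(stride)
        self.pad = tuple(x // 2 for x in k)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.pad)


class ConvTranspose3d(Module):
    def __init__(self, rng, c_in: int, c_out: int, kernel, stride=1, bias=True):
        k = _triple(kernel)
        fan_in = c_in * k[0] * k[1] * k[2]
        self.weight = Parameter(kaiming_normal(rng, (c_in, c_out, *k), fan_in))
        self.bias = Parameter(np.zeros(c_out, dtype=DTYPE)) if bias else None
        self.stride = _triple(stride)
        self.pad = tuple(x // 2 for x in k)

    def __call__(self, x: Tensor, out_spatial: tuple[int, int, int]) -> Tensor:
        return conv_transpose3d(x, self.weight, self.bias, self.stride,
                                self.pad, out_spatial)


# --------------------------------------------------------------------------
# Optimiser
# --------------------------------------------------------------------------

class SGD:
    """SGD with classical momentum and decoupled-from-nothing weight decay
    (decay added to the gradient, as in standard deep-learning practice).

    With a zero momentum buffer the first step equals a vanilla SGD step.
    """

    def __init__(self, params: Iterable[Parameter], lr: float,
                 momentum: float = 0.0, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._buffers = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, buf in zip(self.params, self._buffers):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= (self.lr * buf).astype(DTYPE)
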