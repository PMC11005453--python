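"""Minimal reverse-mode automatic differentiation engine on NumPy.

Provides exactly the primitives the segmentation network needs: broadcasting
elementwise arithmetic, batched matmul, (grouped/strided) 2-D convolution, a
2x2-stride-2 transposed convolution, bilinear grid resampling, reductions,
leaky rectifiers, dropout, and the layer classes built on them (Linear,
Conv2d, InstanceNorm2d, LayerNorm). Gradients are accumulated by walking the
tape in reverse topological order; every stochastic choice draws from an
explicit ``numpy.random.Generator`` so whole runs are reproducible from one
seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Module",
    "ModuleList",
    "Linear",
    "Conv2d",
    "ConvTranspose2x2",
    "InstanceNorm2d",
    "LayerNorm",
    "Dropout",
    "SGD",
    "concat",
    "matmul",
    "softmax",
    "leaky_relu",
    "relu",
    "bilinear_resize",
    "trunc_normal",
]


# ---------------------------------------------------------------------------
# Tensor and tape
# ---------------------------------------------------------------------------

class Tensor:
    """An n-d array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- shape helpers ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- autograd ---------------------------------------------------------
    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __truediv__(self, other):
        return div(self, other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _accum(t: Tensor, g: np.ndarray) -> None:
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# Elementwise and linear-algebra primitives
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g, a.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g, b.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g * b.data, a.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(g * a.data, b.shape))

    return _make(data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data / b.data

    def backward(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g / b.data, a.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(-g * a.data / (b.data ** 2), b.shape))

    return _make(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** p

    def backward(g):
        if a.requires_grad:
            _accum(a, g * p * a.data ** (p - 1))

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        if a.requires_grad:
            _accum(a, g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            _accum(a, g / a.data)

    return _make(data, (a,), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            _accum(a, _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape))
        if b.requires_grad:
            _accum(b, _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape))

    return _make(data, (a, b), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.shape
    data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            _accum(a, g.reshape(old))

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        if a.requires_grad:
            _accum(a, g.transpose(inv))

    return _make(data, (a,), backward)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                _accum(t, g[tuple(sl)])

    return _make(data, tensors, backward)


def narrow(a, axis: int, start: int, length: int) -> Tensor:
    a = _as_tensor(a)
    sl = [slice(None)] * a.ndim
    sl[axis] = slice(start, start + length)
    sl = tuple(sl)
    data = a.data[sl]

    def backward(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            full[sl] = g
            _accum(a, full)

    return _make(data, (a,), backward)


def split(a, sizes, axis: int):
    """Split along ``axis`` into chunks of the given sizes."""
    out, pos = [], 0
    for s in sizes:
        out.append(narrow(a, axis, pos, s))
        pos += s
    return out


def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            _accum(a, np.broadcast_to(g, a.shape).copy())
            return
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.shape).copy())

    return _make(data, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = _as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis, keepdims), 1.0 / n)


def leaky_relu(a, negative_slope: float = 0.01) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, negative_slope * a.data)

    def backward(g):
        if a.requires_grad:
            _accum(a, g * np.where(mask, 1.0, negative_slope))

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    return leaky_relu(a, 0.0)


def softmax(a, axis: int = -1) -> Tensor:
    """Numerically stable softmax built from primitives (shift is constant)."""
    a = _as_tensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))
    e = exp(a - shift)
    return div(e, tsum(e, axis=axis, keepdims=True))


def dropout(a, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    a = _as_tensor(a)
    if not training or p <= 0.0:
        return a
    keep = (rng.random(a.shape) >= p) / (1.0 - p)

    def backward(g):
        if a.requires_grad:
            _accum(a, g * keep)

    return _make(a.data * keep, (a,), backward)


# ---------------------------------------------------------------------------
# Convolution primitives
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return win[:, :, ::sh, ::sw]  # (B, C, Ho, Wo, kh, kw)


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation. ``groups`` must be 1 or equal to C_in (depthwise)."""
    x, w = _as_tensor(x), _as_tensor(w)
    B, C, H, W = x.shape
    if groups == 1:
        Co, Ci, kh, kw = w.shape
        if Ci != C:
            raise ValueError(f"conv2d: weight expects {Ci} channels, input has {C}")
    elif groups == C:
        Co, one, kh, kw = w.shape
        if Co != C or one != 1:
            raise ValueError("depthwise conv2d: weight must be (C, 1, kh, kw)")
    else:
        raise ValueError("conv2d supports groups=1 or depthwise groups=C_in")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    Hp, Wp = xp.shape[2:]
    if Hp < kh or Wp < kw:
        raise ValueError(
            f"conv2d: spatial size {(H, W)} smaller than kernel {kh} after padding")
    cols = _im2col(xp, kh, kw, s, s)
    Ho, Wo = cols.shape[2], cols.shape[3]
    if groups == 1:
        data = np.einsum("bcijuv,ocuv->boij", cols, w.data, optimize=True)
    else:
        data = np.einsum("bcijuv,cuv->bcij", cols, w.data[:, 0], optimize=True)
    bias = _as_tensor(b) if b is not None else None
    if bias is not None:
        data = data + bias.data[None, :, None, None]

    def backward(g):
        if w.requires_grad:
            if groups == 1:
                gw = np.einsum("boij,bcijuv->ocuv", g, cols, optimize=True)
            else:
                gw = np.einsum("bcij,bcijuv->cuv", g, cols, optimize=True)[:, None]
            _accum(w, gw)
        if bias is not None and bias.requires_grad:
            _accum(bias, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for u in range(kh):
                for v in range(kw):
                    if groups == 1:
                        t = np.einsum("boij,oc->bcij", g, w.data[:, :, u, v],
                                      optimize=True)
                    else:
                        t = g * w.data[:, 0, u, v][None, :, None, None]
                    gxp[:, :, u:u + s * Ho:s, v:v + s * Wo:s] += t
            _accum(x, gxp[:, :, p:p + H, p:p + W] if p else gxp)

    parents = (x, w) if bias is None else (x, w, bias)
    return _make(data, parents, backward)


def conv_transpose2x2(x, w, b=None) -> Tensor:
    """Transposed convolution with kernel 2, stride 2 (exact spatial doubling).

    ``w`` has shape (C_in, C_out, 2, 2); output pixel (2i+u, 2j+v) receives
    ``sum_c x[b,c,i,j] * w[c,o,u,v]``.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    B, C, H, W = x.shape
    Ci, Co = w.shape[:2]
    if Ci != C:
        raise ValueError(f"conv_transpose2x2: weight expects {Ci} channels, got {C}")
    y6 = np.einsum("bcij,couv->boiujv", x.data, w.data, optimize=True)
    data = y6.reshape(B, Co, 2 * H, 2 * W)
    bias = _as_tensor(b) if b is not None else None
    if bias is not None:
        data = data + bias.data[None, :, None, None]

    def backward(g):
        g6 = g.reshape(B, Co, H, 2, W, 2)
        if x.requires_grad:
            _accum(x, np.einsum("boiujv,couv->bcij", g6, w.data, optimize=True))
        if w.requires_grad:
            _accum(w, np.einsum("boiujv,bcij->couv", g6, x.data, optimize=True))
        if bias is not None and bias.requires_grad:
            _accum(bias, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if bias is None else (x, w, bias)
    return _make(data, parents, backward)


_RESIZE_CACHE: dict = {}


def _resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Bilinear interpolation matrix (align-corners endpoint convention)."""
    key = (n_in, n_out)
    if key not in _RESIZE_CACHE:
        A = np.zeros((n_out, n_in))
        for o in range(n_out):
            pos = o * (n_in - 1) / (n_out - 1) if n_out > 1 else (n_in - 1) / 2.0
            i0 = int(np.floor(pos))
            i1 = min(i0 + 1, n_in - 1)
            f = pos - i0
            A[o, i0] += 1.0 - f
            A[o, i1] += f
        _RESIZE_CACHE[key] = A
    return _RESIZE_CACHE[key]


def bilinear_resize(x, out_hw) -> Tensor:
    """Resample a (B, C, H, W) tensor to ``out_hw`` with separable bilinear maps."""
    x = _as_tensor(x)
    B, C, H, W = x.shape
    Ho, Wo = out_hw
    if (Ho, Wo) == (H, W):
        return x
    Ah, Aw = _resize_matrix(H, Ho), _resize_matrix(W, Wo)
    data = np.einsum("oh,bchw,pw->bcop", Ah, x.data, Aw, optimize=True)

    def backward(g):
        if x.requires_grad:
            _accum(x, np.einsum("oh,bcop,pw->bchw", Ah, g, Aw, optimize=True))

    return _make(data, (x,), backward)


# ---------------------------------------------------------------------------
# Initialisation
# ---------------------------------------------------------------------------

def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) resampled until all draws lie within two deviations."""
    vals = rng.standard_normal(shape) * std
    for _ in range(8):
        bad = np.abs(vals) > 2 * std
        if not bad.any():
            break
        vals[bad] = rng.standard_normal(int(bad.sum())) * std
    return np.clip(vals, -2 * std, 2 * std)


def he_normal(rng: np.random.Generator, shape, fan_in: int,
              slope: float = 0.01) -> np.ndarray:
    gain = np.sqrt(2.0 / (1.0 + slope ** 2))
    return rng.standard_normal(shape) * gain / np.sqrt(fan_in)


# ---------------------------------------------------------------------------
# Modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: recursive parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            path = f"{prefix}{name}"
            if isinstance(v, Tensor) and v.requires_grad:
                yield path, v
            elif isinstance(v, Module):
                yield from v.named_parameters(path + ".")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{path}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, flag: bool = True):
        for m in self.modules():
            m.training = flag
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)[:5]}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float64).copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self.items = list(mods)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)

    def append(self, m):
        self.items.append(m)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 init: str = "trunc_normal"):
        super().__init__()
        if init == "trunc_normal":
            w = trunc_normal(rng, (n_in, n_out))
        else:
            w = he_normal(rng, (n_in, n_out), fan_in=n_in)
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return matmul(x, self.w) + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 init: str = "he"):
        super().__init__()
        self.stride, self.padding, self.groups = stride, padding, groups
        if groups == 1:
            shape, fan_in = (c_out, c_in, kernel, kernel), c_in * kernel * kernel
        else:
            shape, fan_in = (c_out, 1, kernel, kernel), kernel * kernel
        w = (he_normal(rng, shape, fan_in) if init == "he"
             else trunc_normal(rng, shape))
        self.w = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.stride, self.padding, self.groups)


class ConvTranspose2x2(Module):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        self.w = Tensor(he_normal(rng, (c_in, c_out, 2, 2), fan_in=c_in),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2x2(x, self.w, self.b)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalisation over the spatial axes."""

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        m = tmean(x, axis=(2, 3), keepdims=True)
        centred = x - m
        v = tmean(mul(centred, centred), axis=(2, 3), keepdims=True)
        y = div(centred, power(v + self.eps, 0.5))
        g = reshape(self.gamma, (1, -1, 1, 1))
        b = reshape(self.beta, (1, -1, 1, 1))
        return mul(y, g) + b


class LayerNorm(Module):
    """Normalisation over the last (feature) axis of a token sequence."""

    def __init__(self, width: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(width), requires_grad=True)
        self.beta = Tensor(np.zeros(width), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        m = tmean(x, axis=-1, keepdims=True)
        centred = x - m
        v = tmean(mul(centred, centred), axis=-1, keepdims=True)
        return mul(div(centred, power(v + self.eps, 0.5)), self.gamma) + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return dropout(x, self.p, self.rng, self.training)


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class SGD:
    """Stochastic gradient descent with (Nesterov) momentum."""

    def __init__(self, params, lr: float, momentum: float = 0.99,
                 nesterov: bool = True, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.nesterov = nesterov
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            update = g + self.momentum * v if self.nesterov else v
            p.data -= self.lr * update
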