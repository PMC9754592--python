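"""Minimal numpy neural-network layer framework with explicit backward passes.

Every layer is a :class:`Module` that owns named :class:`Param` objects and
child modules.  ``forward`` pushes whatever it needs onto an internal cache
stack and ``backward`` pops it, so one module instance may be applied several
times per step (weight sharing / recurrence) as long as backward calls mirror
forward calls in reverse order.  All arrays are float64.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "ModuleList",
    "Conv2d",
    "ConvTranspose2d",
    "PReLU",
    "ReLU",
    "Sigmoid",
    "GlobalAvgPool",
    "Adam",
    "l1_loss",
]


class Param:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Module:
    """Base class: auto-registers Param/Module attributes, mirrors torch.nn."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_cache", [])

    def __setattr__(self, name, value):
        if isinstance(value, Param):
            self._params[name] = value
        elif isinstance(value, (Module, ModuleList)):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- parameter traversal ------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- (de)serialization --------------------------------------------------
    def state_dict(self) -> dict:
        return {name: p.value.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)} extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.value.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.value.shape}")
            p.value = arr.copy()
            p.grad = np.zeros_like(p.value)

    # -- interface ----------------------------------------------------------
    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def depth(self) -> int:
        """Conv/deconv layers on the longest input->output path (default 0)."""
        return 0


class ModuleList:
    """Ordered container of modules, registered under their index."""

    def __init__(self, modules=()):
        self._items = list(modules)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]

    def append(self, mod):
        self._items.append(mod)

    def named_parameters(self, prefix: str = ""):
        for i, mod in enumerate(self._items):
            yield from mod.named_parameters(f"{prefix}{i}.")


# ---------------------------------------------------------------------------
# im2col / col2im (numba-accelerated when available)
# ---------------------------------------------------------------------------

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(fn):
            return fn
        return deco(a[0]) if a and callable(a[0]) else deco


@_njit(cache=True)
def _im2col_kernel(xp, k, stride, ho, wo, cols):  # pragma: no cover - jitted
    b, c = xp.shape[0], xp.shape[1]
    for bi in range(b):
        for ci in range(c):
            for i in range(k):
                for j in range(k):
                    row = ci * k * k + i * k + j
                    for oi in range(ho):
                        src_i = oi * stride + i
                        for oj in range(wo):
                            cols[bi, row, oi * wo + oj] = xp[bi, ci, src_i,
                                                             oj * stride + j]


@_njit(cache=True)
def _col2im_kernel(cols, k, stride, ho, wo, out):  # pragma: no cover - jitted
    b, c = out.shape[0], out.shape[1]
    for bi in range(b):
        for ci in range(c):
            for i in range(k):
                for j in range(k):
                    row = ci * k * k + i * k + j
                    for oi in range(ho):
                        dst_i = oi * stride + i
                        for oj in range(wo):
                            out[bi, ci, dst_i, oj * stride + j] += \
                                cols[bi, row, oi * wo + oj]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    """(B,C,H,W) -> (B, C*k*k, L) patch matrix."""
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    x = np.ascontiguousarray(x)
    hp, wp = x.shape[2], x.shape[3]
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    cols = np.empty((b, c * k * k, ho * wo), dtype=x.dtype)
    _im2col_kernel(x, k, stride, ho, wo, cols)
    return cols, (ho, wo)


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int):
    """Scatter-add inverse of _im2col back to (B,C,H,W)."""
    b, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    out = np.zeros((b, c, hp, wp), dtype=cols.dtype)
    _col2im_kernel(np.ascontiguousarray(cols), k, stride, ho, wo, out)
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """Strided 2D convolution (cross-correlation), NCHW."""

    def __init__(self, cin, cout, k, stride=1, pad=0, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        rng = rng or np.random.default_rng(0)
        self.weight = Param(_kaiming(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Param(np.zeros(cout)) if bias else None
        self.has_bias = bias

    def forward(self, x):
        b = x.shape[0]
        cols, (ho, wo) = _im2col(x, self.k, self.stride, self.pad)
        wmat = self.weight.value.reshape(self.cout, -1)
        y = np.matmul(wmat, cols).reshape(b, self.cout, ho, wo)
        if self.has_bias:
            y += self.bias.value[None, :, None, None]
        self._cache.append((x.shape, cols))
        return y

    def backward(self, dy):
        x_shape, cols = self._cache.pop()
        b = dy.shape[0]
        if self.has_bias:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dyf = np.ascontiguousarray(dy.reshape(b, self.cout, -1))
        wmat = self.weight.value.reshape(self.cout, -1)
        dw = np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0)
        self.weight.grad += dw.reshape(self.weight.value.shape)
        dcols = np.matmul(wmat.T, dyf)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)

    def depth(self) -> int:
        return 1


class ConvTranspose2d(Module):
    """Transposed convolution; output size = (H-1)*stride - 2*pad + k."""

    def __init__(self, cin, cout, k, stride=1, pad=0, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        rng = rng or np.random.default_rng(0)
        # weight layout matches torch: (cin, cout, k, k)
        self.weight = Param(_kaiming(rng, (cin, cout, k, k), cin * k * k))
        self.bias = Param(np.zeros(cout)) if bias else None
        self.has_bias = bias

    def out_shape(self, h, w):
        s, p, k = self.stride, self.pad, self.k
        return (h - 1) * s - 2 * p + k, (w - 1) * s - 2 * p + k

    def forward(self, x):
        b, c, h, w = x.shape
        ho, wo = self.out_shape(h, w)
        x = np.ascontiguousarray(x)
        wmat = self.weight.value.reshape(self.cin, -1)  # (cin, cout*k*k)
        cols = np.matmul(wmat.T, x.reshape(b, c, h * w))
        y = _col2im(cols, (b, self.cout, ho, wo), self.k, self.stride, self.pad)
        if self.has_bias:
            y += self.bias.value[None, :, None, None]
        self._cache.append((x, (ho, wo)))
        return y

    def backward(self, dy):
        x, _ = self._cache.pop()
        b, c, h, w = x.shape
        if self.has_bias:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dcols, _ = _im2col(dy, self.k, self.stride, self.pad)  # (b, cout*k*k, h*w)
        xf = x.reshape(b, c, h * w)
        dw = np.matmul(xf, dcols.transpose(0, 2, 1)).sum(axis=0)
        self.weight.grad += dw.reshape(self.weight.value.shape)
        dx = np.matmul(self.weight.value.reshape(self.cin, -1), dcols)
        return dx.reshape(x.shape)

    def depth(self) -> int:
        return 1


class PReLU(Module):
    """Parametric ReLU with a single shared slope (torch default)."""

    def __init__(self, init: float = 0.25):
        super().__init__()
        self.slope = Param(np.array([init]))

    def forward(self, x):
        self._cache.append(x)
        a = self.slope.value[0]
        return np.where(x > 0, x, a * x)

    def backward(self, dy):
        x = self._cache.pop()
        neg = x <= 0
        self.slope.grad += np.array([np.sum(dy * x * neg)])
        a = self.slope.value[0]
        return dy * np.where(neg, a, 1.0)


class ReLU(Module):
    def forward(self, x):
        mask = x > 0
        self._cache.append(mask)
        return x * mask

    def backward(self, dy):
        return dy * self._cache.pop()


class Sigmoid(Module):
    def forward(self, x):
        y = 1.0 / (1.0 + np.exp(-x))
        self._cache.append(y)
        return y

    def backward(self, dy):
        y = self._cache.pop()
        return dy * y * (1.0 - y)


class GlobalAvgPool(Module):
    """(B,C,H,W) -> (B,C,1,1) mean pool."""

    def forward(self, x):
        self._cache.append(x.shape)
        return x.mean(axis=(2, 3), keepdims=True)

    def backward(self, dy):
        b, c, h, w = self._cache.pop()
        return np.broadcast_to(dy / (h * w), (b, c, h, w)).copy()


# ---------------------------------------------------------------------------
# Optimizer / loss
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def l1_loss(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error; returns (loss, dloss/dpred)."""
    diff = pred - target
    loss = float(np.mean(np.abs(diff)))
    grad = np.sign(diff) / diff.size
    return loss, grad
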