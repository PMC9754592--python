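"""Separable Catmull-Rom bicubic resampling as explicit weight matrices.

The dialect is pinned: cubic convolution kernel with a = -0.5, pixel-center
alignment (output pixel ``i`` samples input coordinate ``(i + 0.5)/f - 0.5``),
replicate edge handling, and kernel widening (antialiasing) when downscaling.
Representing the resampler as a dense matrix per axis makes the operation and
its adjoint (needed for backprop through the fixed upsampling path) exact.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .nn import Module

__all__ = ["bicubic_kernel", "resize_matrix", "bicubic_resize", "BicubicResize"]


def bicubic_kernel(t: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys cubic convolution kernel, support [-2, 2]."""
    t = np.abs(t)
    out = np.zeros_like(t)
    m1 = t <= 1
    m2 = (t > 1) & (t < 2)
    out[m1] = (a + 2) * t[m1] ** 3 - (a + 3) * t[m1] ** 2 + 1
    out[m2] = a * t[m2] ** 3 - 5 * a * t[m2] ** 2 + 8 * a * t[m2] - 4 * a
    return out


@lru_cache(maxsize=256)
def resize_matrix(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) row-stochastic resampling matrix for one axis."""
    if n_in < 1 or n_out < 1:
        raise ValueError("sizes must be positive")
    scale = n_in / n_out
    aa = max(scale, 1.0)  # kernel stretch for antialiased downscale
    support = 2.0 * aa
    mat = np.zeros((n_out, n_in))
    for i in range(n_out):
        center = (i + 0.5) * scale - 0.5
        lo = int(np.floor(center - support)) + 1
        hi = int(np.floor(center + support))
        taps = np.arange(lo, hi + 1)
        w = bicubic_kernel((taps - center) / aa)
        w = w / w.sum()
        taps = np.clip(taps, 0, n_in - 1)  # replicate edges
        np.add.at(mat[i], taps, w)
    return mat


def bicubic_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Resize the trailing two axes of ``img`` to (out_h, out_w)."""
    ah = resize_matrix(img.shape[-2], out_h)
    aw = resize_matrix(img.shape[-1], out_w)
    return np.matmul(np.matmul(ah, img), aw.T)


class BicubicResize(Module):
    """Fixed (non-trainable) bicubic rescale by an integer factor, NCHW."""

    def __init__(self, factor: int):
        super().__init__()
        if factor < 1:
            raise ValueError("factor must be >= 1")
        self.factor = factor

    def forward(self, x):
        if self.factor == 1:
            self._cache.append(None)
            return x
        h, w = x.shape[-2], x.shape[-1]
        self._cache.append((h, w))
        return bicubic_resize(x, h * self.factor, w * self.factor)

    def backward(self, dy):
        shape = self._cache.pop()
        if shape is None:
            return dy
        h, w = shape
        ah = resize_matrix(h, h * self.factor)
        aw = resize_matrix(w, w * self.factor)
        # adjoint of the linear resize
        return np.matmul(np.matmul(ah.T, dy), aw)
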