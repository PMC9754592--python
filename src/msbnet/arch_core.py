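"""Shared primitives: per-scale resampling geometry, basic blocks, auditing.

The kernel/stride/pad triples satisfy ``kernel - 2*pad = stride = scale`` so a
transposed convolution multiplies the spatial size exactly by ``scale`` and a
strided convolution divides it exactly (for divisible inputs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import Conv2d, ConvTranspose2d, Module, PReLU, ReLU

__all__ = [
    "ScaleConfig",
    "make_scale_config",
    "UpsampleLayer",
    "DownsampleLayer",
    "ResidualGroup",
    "AuditReport",
    "count_parameters",
]

# kernel sizes for scales 1..4; stride = scale, pad = (kernel - scale) // 2
_KERNELS = {1: 3, 2: 6, 3: 7, 4: 8}


@dataclass(frozen=True)
class ScaleConfig:
    scale: int
    kernel: int
    stride: int
    pad: int

    def __post_init__(self):
        if min(self.scale, self.kernel, self.stride) < 1 or self.pad < 0:
            raise ValueError("ScaleConfig fields must be positive (pad may be 0)")
        if self.kernel - 2 * self.pad != self.stride or self.stride != self.scale:
            raise ValueError(
                f"invalid geometry: kernel - 2*pad must equal stride = scale, got {self}")


def make_scale_config(scale: int) -> ScaleConfig:
    """Return the canonical kernel/stride/pad triple for a supported scale."""
    if scale not in _KERNELS:
        raise ValueError(f"unsupported scale {scale}; allowed scales are {sorted(_KERNELS)}")
    k = _KERNELS[scale]
    return ScaleConfig(scale=scale, kernel=k, stride=scale, pad=(k - scale) // 2)


class UpsampleLayer(Module):
    """Transposed convolution + PReLU multiplying spatial dims by cfg.scale."""

    def __init__(self, cfg: ScaleConfig, channels: int = 64,
                 rng: np.random.Generator | None = None, activation: bool = True):
        super().__init__()
        self.cfg = cfg
        self.deconv = ConvTranspose2d(channels, channels, cfg.kernel,
                                      stride=cfg.stride, pad=cfg.pad, rng=rng)
        self.act = PReLU() if activation else None

    def forward(self, x):
        if not np.all(np.isfinite(x)):
            raise ValueError("non-finite input to UpsampleLayer")
        y = self.deconv(x)
        return self.act(y) if self.act is not None else y

    def backward(self, dy):
        if self.act is not None:
            dy = self.act.backward(dy)
        return self.deconv.backward(dy)

    def depth(self) -> int:
        return 1


class DownsampleLayer(Module):
    """Strided convolution + PReLU dividing spatial dims by cfg.scale."""

    def __init__(self, cfg: ScaleConfig, channels: int = 64,
                 rng: np.random.Generator | None = None, activation: bool = True):
        super().__init__()
        self.cfg = cfg
        self.conv = Conv2d(channels, channels, cfg.kernel,
                           stride=cfg.stride, pad=cfg.pad, rng=rng)
        self.act = PReLU() if activation else None

    def forward(self, x):
        h, w = x.shape[-2], x.shape[-1]
        s = self.cfg.scale
        if h % s or w % s:
            raise ValueError(
                f"spatial dims ({h}, {w}) not divisible by scale {s}; pad the input first")
        y = self.conv(x)
        return self.act(y) if self.act is not None else y

    def backward(self, dy):
        if self.act is not None:
            dy = self.act.backward(dy)
        return self.conv.backward(dy)

    def depth(self) -> int:
        return 1


class ResidualGroup(Module):
    """x + f(x) with f = conv3x3 -> ReLU -> conv3x3 (ResNet-style, shape kept)."""

    def __init__(self, channels: int = 64, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, 3, stride=1, pad=1, rng=rng)
        self.relu = ReLU()
        self.conv2 = Conv2d(channels, channels, 3, stride=1, pad=1, rng=rng)

    def forward(self, x):
        return x + self.conv2(self.relu(self.conv1(x)))

    def backward(self, dy):
        dres = self.conv1.backward(self.relu.backward(self.conv2.backward(dy)))
        return dy + dres

    def depth(self) -> int:
        return 2


@dataclass
class AuditReport:
    total_params: int
    params_K: int
    per_module_params: dict = field(default_factory=dict)
    depth: int = 0

    def __post_init__(self):
        if sum(self.per_module_params.values()) != self.total_params:
            raise ValueError("per-module parameter counts do not sum to total")
        if self.params_K != round(self.total_params / 1000):
            raise ValueError("params_K must be the K-rounded total")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def count_parameters(model: Module, top_level: bool = True) -> AuditReport:
    """Count every trainable weight/bias exactly once, with a per-child split."""
    per = {}
    for name, mod in model._modules.items():
        if isinstance(mod, Module):
            per[name] = mod.n_params()
        else:  # ModuleList
            per[name] = sum(p.size for _, p in mod.named_parameters())
    for name, p in model._params.items():
        per[name] = p.size
    total = model.n_params()
    return AuditReport(total_params=total, params_K=round(total / 1000),
                       per_module_params=per, depth=model.depth())
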