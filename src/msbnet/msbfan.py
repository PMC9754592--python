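"""Bidirectional recurrent spatio-temporal fusion attention network.

One recurrence step (STAM) fuses two streams for a neighbor offset ``k``:

* temporal: concat(target, neighbor) -> shallow conv -> residual blocks (TEB)
  -> shared learned upsample to the HR domain;
* spatial: the recurrent LR feature -> multi-scale back-projection backbone
  (SEB) -> HR feature.

A squeeze-excitation gate over the concatenated pair plus a 1x1 fusion conv
produces the step's HR feature H_k (STAB); a shared strided conv returns it to
the LR domain as the next recurrent feature, emitted identically for the
forward and backward streams (DB).  All STAM weights are shared across steps.
Neighbors are visited nearest-first, alternating past/future; the final image
is a 3x3 conv over the concatenated H_k plus a bicubic skip of the target.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from math import gcd

import numpy as np
import yaml

from .arch_core import ResidualGroup, UpsampleLayer, DownsampleLayer, make_scale_config
from .msbpn import (ChannelSelection, DenseCompress, DownProjection,
                    ProjectionSpec, ScaleBranch, UpProjection)
from .nn import Conv2d, GlobalAvgPool, Module, ModuleList, PReLU, ReLU, Sigmoid
from .resize import BicubicResize

__all__ = [
    "SliceSequence",
    "MsbfanConfig",
    "ShallowTarget",
    "ShallowPair",
    "TemporalBlock",
    "SpatialBlock",
    "DbpnSpatialBlock",
    "FusionAttention",
    "FusionResidual",
    "DownsampleBlock",
    "Reconstruction",
    "MSBFAN",
    "build_msbfan",
    "neighbor_offsets",
    "save_config",
    "load_config",
]


@dataclass
class SliceSequence:
    """Ordered same-shape grayscale slices with a designated target index."""

    slices: list
    target_index: int
    offset_index: dict | None = None  # optional explicit offset -> list index

    def __post_init__(self):
        if not self.slices:
            raise ValueError("empty slice sequence")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1:
            raise ValueError(f"slices must share spatial dims, got {sorted(shapes)}")
        if not 0 <= self.target_index < len(self.slices):
            raise ValueError("target index out of bounds")

    @property
    def target(self) -> np.ndarray:
        return self.slices[self.target_index]

    def neighbor(self, offset: int) -> np.ndarray:
        if self.offset_index is not None:
            return self.slices[self.offset_index[offset]]
        i = self.target_index + offset
        if not 0 <= i < len(self.slices):
            raise IndexError(f"offset {offset} outside the sequence")
        return self.slices[i]

    @classmethod
    def from_volume(cls, voxels: np.ndarray, target_slice: int, seq_len: int):
        """Centered window along the depth axis, replicate-padded at the edges."""
        depth = voxels.shape[2]
        if not 0 <= target_slice < depth:
            raise ValueError("target slice out of bounds")
        half = (seq_len - 1) // 2
        extra = seq_len - 1 - half  # past gets the odd slot for even lengths
        idx = [min(max(target_slice + k, 0), depth - 1)
               for k in range(-extra, half + 1)]
        return cls(slices=[voxels[:, :, i] for i in idx], target_index=extra)

    @classmethod
    def from_volume_offsets(cls, voxels: np.ndarray, target_slice: int, offsets):
        """Window holding the target plus exactly the requested offsets."""
        depth = voxels.shape[2]
        if not 0 <= target_slice < depth:
            raise ValueError("target slice out of bounds")
        ordered = sorted(set(offsets) | {0})
        idx = [min(max(target_slice + k, 0), depth - 1) for k in ordered]
        omap = {k: i for i, k in enumerate(ordered)}
        return cls(slices=[voxels[:, :, i] for i in idx],
                   target_index=omap[0], offset_index=omap)


def neighbor_offsets(seq_len: int, mode: str = "bidirectional") -> list:
    """Offsets visited per step: nearest-first, past before future."""
    if seq_len < 1:
        raise ValueError("sequence length must be >= 1")
    if mode == "bidirectional":
        out = []
        for d in range(1, seq_len):
            out.extend([-d, d])
        return out[: seq_len - 1]
    if mode == "forward":   # past slices feed the forward stream
        return [-d for d in range(1, seq_len)]
    if mode == "backward":  # future slices feed the backward stream
        return [d for d in range(1, seq_len)]
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class MsbfanConfig:
    task_scale: int = 4
    seq_len: int = 7
    m: int = 1
    n: int = 1
    channels: int = 64
    teb_blocks: int = 9
    attention_reduction: int = 16
    mode: str = "bidirectional"          # bidirectional | forward | backward
    fusion: str = "attention"            # attention | residual  (FA -> RL swap)
    seb_kind: str = "msbpn"              # msbpn | dbpn          (M -> D swap)
    dbpn_stages: int = 3
    recon_slots: int = 0                 # 0 => one per neighbor offset
    offsets: tuple | None = None         # explicit neighbor offsets (overrides mode)

    def __post_init__(self):
        if self.seq_len < 1:
            raise ValueError("seq_len must be >= 1")
        if self.offsets is not None:
            self.offsets = tuple(self.offsets)
        if self.recon_slots == 0:
            n_off = (len(self.offsets) if self.offsets is not None
                     else self.seq_len - 1)
            self.recon_slots = max(1, n_off)

    def spec(self) -> ProjectionSpec:
        return ProjectionSpec(task_scale=self.task_scale, m=self.m, n=self.n,
                              channels=self.channels)


def save_config(cfg: MsbfanConfig, path):
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)


def load_config(path) -> MsbfanConfig:
    with open(path) as fh:
        return MsbfanConfig(**yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Blocks
# ---------------------------------------------------------------------------

class ShallowTarget(Module):
    """S_t: 3x3 conv (1 -> c) + PReLU on the target slice."""

    def __init__(self, channels, rng=None):
        super().__init__()
        self.conv = Conv2d(1, channels, 3, stride=1, pad=1, rng=rng)
        self.act = PReLU()

    def forward(self, x):
        return self.act(self.conv(x))

    def backward(self, dy):
        return self.conv.backward(self.act.backward(dy))

    def depth(self):
        return 1


class ShallowPair(Module):
    """T_{t+k}: 3x3 conv (2 -> c) + PReLU on the ordered (target, neighbor) pair."""

    def __init__(self, channels, rng=None):
        super().__init__()
        self.conv = Conv2d(2, channels, 3, stride=1, pad=1, rng=rng)
        self.act = PReLU()

    def forward(self, target, neighbor):
        if target.shape != neighbor.shape:
            raise ValueError("target/neighbor shape mismatch")
        return self.act(self.conv(np.concatenate([target, neighbor], axis=1)))

    def backward(self, dy):
        dcat = self.conv.backward(self.act.backward(dy))
        return np.split(dcat, 2, axis=1)

    def depth(self):
        return 1


class TemporalBlock(Module):
    """TEB: a stack of residual groups (shape preserved)."""

    def __init__(self, channels, blocks=9, rng=None):
        super().__init__()
        self.groups = ModuleList([ResidualGroup(channels, rng=rng)
                                  for _ in range(blocks)])

    def forward(self, x):
        for g in self.groups:
            x = g(x)
        return x

    def backward(self, dy):
        for g in reversed(list(self.groups)):
            dy = g.backward(dy)
        return dy

    def depth(self):
        return sum(g.depth() for g in self.groups)


class SpatialBlock(Module):
    """SEB: the MSBPN backbone over an LR feature, up to channel selection."""

    def __init__(self, spec: ProjectionSpec, rng=None):
        super().__init__()
        self.spec = spec
        c, g = spec.channels, spec.task_scale
        self.up0 = UpsampleLayer(make_scale_config(g), c, rng=rng)
        self.bicubic = BicubicResize(g)
        self.fuse = DenseCompress(2, c, rng=rng)
        self.branches = ModuleList([ScaleBranch(s, spec, rng=rng)
                                    for s in spec.scales])
        self.select = ChannelSelection(len(spec.scales), c, rng=rng)

    def forward(self, S):
        H0 = self.fuse([self.up0(S), self.bicubic(S)])
        return self.select([br(H0) for br in self.branches])

    def backward(self, dy):
        douts = self.select.backward(dy)
        dH0 = None
        for br, do in zip(reversed(self.branches._items), reversed(douts)):
            d = br.backward(do)
            dH0 = d if dH0 is None else dH0 + d
        dU, dB = self.fuse.backward(dH0)
        return self.up0.backward(dU) + self.bicubic.backward(dB)

    def depth(self):
        return 2 + max(br.depth() for br in self.branches) + 1


class DbpnSpatialBlock(Module):
    """Single-scale DBPN-style SEB (alternating up/down projections)."""

    def __init__(self, task_scale: int, channels: int, stages: int = 3, rng=None):
        super().__init__()
        cfg = make_scale_config(task_scale)
        ups, downs = [], []
        for _ in range(stages):
            ups.append(UpProjection(cfg, channels, rng=rng))
        for _ in range(stages - 1):
            downs.append(DownProjection(cfg, channels, rng=rng))
        self.ups = ModuleList(ups)
        self.downs = ModuleList(downs)
        self.select = ChannelSelection(stages, channels, rng=rng)
        self.stages = stages

    def forward(self, S):
        hs = []
        x = S
        for i in range(self.stages):
            h = self.ups[i](x)
            hs.append(h)
            if i < self.stages - 1:
                x = self.downs[i](h)
        return self.select(hs)

    def backward(self, dy):
        dhs = self.select.backward(dy)
        dx = None
        for i in range(self.stages - 1, -1, -1):
            dh = dhs[i]
            if i < self.stages - 1 and dx is not None:
                dh = dh + self.downs[i].backward(dx)
            dx = self.ups[i].backward(dh)
        return dx

    def depth(self):
        return 3 * (2 * self.stages - 1) + 1


class FusionAttention(Module):
    """STAB: concat -> SE channel gate -> 1x1 fusion conv to c channels."""

    def __init__(self, channels, reduction=16, rng=None):
        super().__init__()
        c2 = 2 * channels
        mid = max(1, c2 // reduction)
        self.pool = GlobalAvgPool()
        self.fc1 = Conv2d(c2, mid, 1, rng=rng)
        self.relu = ReLU()
        self.fc2 = Conv2d(mid, c2, 1, rng=rng)
        self.sigmoid = Sigmoid()
        self.proj = Conv2d(c2, channels, 1, rng=rng)
        self.channels = channels

    def forward(self, temporal, spatial):
        if temporal.shape != spatial.shape:
            raise ValueError("temporal/spatial feature shape mismatch")
        cat = np.concatenate([temporal, spatial], axis=1)
        gate = self.sigmoid(self.fc2(self.relu(self.fc1(self.pool(cat)))))
        self._cache.append((cat, gate))
        return self.proj(cat * gate)

    def backward(self, dy):
        cat, gate = self._cache.pop()
        dgated = self.proj.backward(dy)
        dcat = dgated * gate
        dgate = (dgated * cat).sum(axis=(2, 3), keepdims=True)
        dz = self.fc1.backward(self.relu.backward(self.fc2.backward(
            self.sigmoid.backward(dgate))))
        dcat = dcat + self.pool.backward(dz)
        return np.split(dcat, 2, axis=1)

    def depth(self):
        return 1  # on the main path only the 1x1 projection


class FusionResidual(Module):
    """Plain residual fusion (the FA -> RL ablation): proj(concat) + spatial."""

    def __init__(self, channels, rng=None):
        super().__init__()
        self.proj = Conv2d(2 * channels, channels, 1, rng=rng)

    def forward(self, temporal, spatial):
        if temporal.shape != spatial.shape:
            raise ValueError("temporal/spatial feature shape mismatch")
        return self.proj(np.concatenate([temporal, spatial], axis=1)) + spatial

    def backward(self, dy):
        dt, ds = np.split(self.proj.backward(dy), 2, axis=1)
        return dt, ds + dy

    def depth(self):
        return 1


class DownsampleBlock(Module):
    """DB: one shared strided conv; emits identical forward/backward features."""

    def __init__(self, task_scale, channels, rng=None):
        super().__init__()
        self.down = DownsampleLayer(make_scale_config(task_scale), channels, rng=rng)

    def forward(self, H):
        S = self.down(H)
        return S, S.copy()

    def backward(self, dS):
        return self.down.backward(dS)

    def depth(self):
        return 1


class Reconstruction(Module):
    """Concat HR features into a single 3x3 conv producing the image."""

    def __init__(self, slots, channels, rng=None):
        super().__init__()
        self.slots = slots
        self.conv = Conv2d(slots * channels, 1, 3, stride=1, pad=1, rng=rng)
        # residual-learning init: the network starts at the bicubic skip
        self.conv.weight.value[...] = 0.0

    def forward(self, hr_list):
        shapes = {h.shape for h in hr_list}
        if len(shapes) != 1:
            raise ValueError("HR features must share shapes")
        feats = list(hr_list)
        k = len(feats)
        while len(feats) < self.slots:  # cycle when run with fewer neighbors
            feats.append(feats[len(feats) % k])
        self._cache.append(k)
        return self.conv(np.concatenate(feats[: self.slots], axis=1))

    def backward(self, dy):
        k = self._cache.pop()
        dcat = self.conv.backward(dy)
        parts = np.split(dcat, self.slots, axis=1)
        grads = [np.zeros_like(parts[0]) for _ in range(k)]
        for i, part in enumerate(parts):
            grads[i % k] += part
        return grads

    def depth(self):
        return 1


# ---------------------------------------------------------------------------
# Full network
# ---------------------------------------------------------------------------

class MSBFAN(Module):
    def __init__(self, cfg: MsbfanConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c, g = cfg.channels, cfg.task_scale
        self.extract_t = ShallowTarget(c, rng=rng)
        self.extract_p = ShallowPair(c, rng=rng)
        self.teb = TemporalBlock(c, cfg.teb_blocks, rng=rng)
        self.teb_up = UpsampleLayer(make_scale_config(g), c, rng=rng)
        if cfg.seb_kind == "msbpn":
            self.seb = SpatialBlock(cfg.spec(), rng=rng)
        elif cfg.seb_kind == "dbpn":
            self.seb = DbpnSpatialBlock(g, c, cfg.dbpn_stages, rng=rng)
        else:
            raise ValueError(f"unknown seb_kind {cfg.seb_kind!r}")
        if cfg.fusion == "attention":
            self.stab = FusionAttention(c, cfg.attention_reduction, rng=rng)
        elif cfg.fusion == "residual":
            self.stab = FusionResidual(c, rng=rng)
        else:
            raise ValueError(f"unknown fusion {cfg.fusion!r}")
        self.db = DownsampleBlock(g, c, rng=rng)
        self.recon = Reconstruction(cfg.recon_slots, c, rng=rng)
        self.bicubic_img = BicubicResize(g)
        self.offsets = (list(cfg.offsets) if cfg.offsets is not None
                        else neighbor_offsets(cfg.seq_len, cfg.mode))

    # -- forward ------------------------------------------------------------
    def forward(self, seq: SliceSequence):
        target = np.asarray(seq.target, dtype=np.float64)[None, None]
        S = self.extract_t(target)
        hs = []
        n = len(self.offsets)
        if n == 0:  # single-slice path: SEB only
            hs.append(self._seb_hr(S))
        for i, k in enumerate(self.offsets):
            neighbor = np.asarray(seq.neighbor(k), dtype=np.float64)[None, None]
            t_feat = self.teb_up(self.teb(self.extract_p(target, neighbor)))
            h = self.stab(t_feat, self._seb_hr(S))
            hs.append(h)
            if i < n - 1:
                S, _ = self.db(h)
        self._cache.append(n)
        return self.recon(hs) + self.bicubic_img(target)

    def _seb_hr(self, S):
        return self.seb(S)

    def backward(self, dy):
        n = self._cache.pop()
        d_target_img = self.bicubic_img.backward(dy)
        dhs = self.recon.backward(dy)
        if n == 0:
            dS = self.seb.backward(dhs[0])
            self.extract_t.backward(dS)
            return d_target_img
        dS_next = None
        for i in range(n - 1, -1, -1):
            dh = dhs[i]
            if i < n - 1 and dS_next is not None:
                dh = dh + self.db.backward(dS_next)
            dt_feat, dSh = self.stab.backward(dh)
            dS = self.seb.backward(dSh)
            dT = self.extract_p.backward(self.teb.backward(self.teb_up.backward(dt_feat)))
            del dT  # gradients w.r.t. input slices are not needed
            dS_next = dS
        self.extract_t.backward(dS_next)
        return d_target_img

    def depth(self):
        per_stam = self.seb.depth() + self.stab.depth() + self.db.depth()
        steps = max(1, len(self.offsets))
        return 1 + steps * per_stam - self.db.depth() + self.recon.depth()

    def required_multiple(self) -> int:
        if self.cfg.seb_kind != "msbpn":
            return 1
        g = self.cfg.task_scale
        req = 1
        for s in self.seb.spec.scales:
            d = s // gcd(s, g)
            req = req * d // gcd(req, d)
        return req

    def sr(self, seq: SliceSequence) -> np.ndarray:
        """Super-resolve the target slice of a sequence (2D in, 2D out)."""
        h, w = seq.target.shape
        mult = self.required_multiple()
        ph, pw = (-h) % mult, (-w) % mult
        if ph or pw:
            padded = [np.pad(np.asarray(s, dtype=np.float64), ((0, ph), (0, pw)),
                             mode="edge") for s in seq.slices]
            seq = SliceSequence(slices=padded, target_index=seq.target_index)
        out = self.forward(seq)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite values in SR output")
        g = self.cfg.task_scale
        return out[0, 0, :g * h, :g * w]


def build_msbfan(cfg: MsbfanConfig, seed: int = 0) -> MSBFAN:
    return MSBFAN(cfg, seed=seed)


class SebConcat(Module):
    """Baseline: all slices channel-concatenated into a single SEB pass.

    Temporal context enters only through the input stacking — no recurrence,
    no temporal stream, no attention.
    """

    def __init__(self, cfg: MsbfanConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        c, g = cfg.channels, cfg.task_scale
        self.feat = Conv2d(cfg.seq_len, c, 3, stride=1, pad=1, rng=rng)
        self.act = PReLU()
        self.seb = SpatialBlock(cfg.spec(), rng=rng)
        self.recon = Conv2d(c, 1, 3, stride=1, pad=1, rng=rng)
        self.recon.weight.value[...] = 0.0  # residual-learning init
        self.bicubic_img = BicubicResize(g)

    def forward(self, seq: SliceSequence):
        stack = np.stack([np.asarray(s, dtype=np.float64) for s in seq.slices])[None]
        target = np.asarray(seq.target, dtype=np.float64)[None, None]
        y = self.recon(self.seb(self.act(self.feat(stack))))
        return y + self.bicubic_img(target)

    def backward(self, dy):
        self.bicubic_img.backward(dy)
        dS = self.seb.backward(self.recon.backward(dy))
        self.feat.backward(self.act.backward(dS))
        return None

    def depth(self):
        return 1 + self.seb.depth() + 1

    def sr(self, seq: SliceSequence) -> np.ndarray:
        out = self.forward(seq)
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite values in SR output")
        return out[0, 0]
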