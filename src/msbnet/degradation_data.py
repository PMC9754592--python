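"""LR/HR pair synthesis, augmentation, patch/sequence sampling, volume I/O.

LR inputs are synthesized from HR references by antialiased Catmull-Rom
bicubic downscaling (see :mod:`msbnet.resize` for the pinned dialect).
Volumes are min-max normalized to [0, 1] and center-cropped in-plane to
dimensions divisible by 12 (lcm of scales 2, 3, 4) so one HR reference serves
every scale.  Axes are (height, width, depth), 0-based, origin top-left.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .msbfan import SliceSequence
from .resize import bicubic_resize

__all__ = [
    "VolumeRecord",
    "TrainSamplePair",
    "normalize_intensities",
    "center_crop_divisible",
    "degrade_bicubic",
    "augment",
    "compose_augment",
    "sample_patch_pair",
    "make_sequence_samples",
    "read_volume",
    "write_volume",
]

N_AUGMENT_OPS = 8  # 4 rotations x optional horizontal flip


@dataclass
class VolumeRecord:
    voxels: np.ndarray  # (height, width, depth) in [0, 1]
    source_id: str = ""
    spacing: tuple | None = None

    def __post_init__(self):
        v = np.asarray(self.voxels, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError(f"expected (height, width, depth) array, got {v.shape}")
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("voxel intensities must lie in [0, 1]; normalize first")
        self.voxels = v

    @property
    def depth(self) -> int:
        return self.voxels.shape[2]


@dataclass
class TrainSamplePair:
    lr_patch: np.ndarray
    hr_patch: np.ndarray
    scale: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        lh, lw = self.lr_patch.shape
        hh, hw = self.hr_patch.shape
        if (hh, hw) != (self.scale * lh, self.scale * lw):
            raise ValueError(
                f"HR patch {self.hr_patch.shape} is not scale x LR patch {self.lr_patch.shape}")


def normalize_intensities(arr: np.ndarray) -> np.ndarray:
    """Per-volume min-max to [0, 1]; constant input maps to all-zeros."""
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = arr.min(), arr.max()
    if hi - lo < 1e-12:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def center_crop_divisible(arr: np.ndarray, mult: int = 12) -> np.ndarray:
    """Center-crop the two leading (in-plane) axes to multiples of ``mult``."""
    h, w = arr.shape[:2]
    nh, nw = (h // mult) * mult, (w // mult) * mult
    if nh == 0 or nw == 0:
        raise ValueError(f"array {arr.shape} too small to crop to multiples of {mult}")
    oh, ow = (h - nh) // 2, (w - nw) // 2
    return arr[oh:oh + nh, ow:ow + nw]


def degrade_bicubic(hr: np.ndarray, s: int) -> np.ndarray:
    """Antialiased bicubic downscale by integer factor ``s`` (values clipped)."""
    if s < 2:
        raise ValueError("downscale factor must be >= 2")
    hr = np.asarray(hr, dtype=np.float64)
    h, w = hr.shape[-2:]
    hc, wc = (h // s) * s, (w // s) * s
    if hc != h or wc != w:  # crop to the largest divisible region
        hr = hr[..., :hc, :wc]
    out = bicubic_resize(hr, hc // s, wc // s)
    return np.clip(out, 0.0, 1.0)


def augment(img: np.ndarray, op_id: int) -> np.ndarray:
    """Apply one of the 8 dihedral ops: rot90 by (op_id % 4), flip if op_id >= 4."""
    if not 0 <= op_id < N_AUGMENT_OPS:
        raise ValueError(f"op_id must be in 0..{N_AUGMENT_OPS - 1}")
    out = np.rot90(img, k=op_id % 4, axes=(-2, -1))
    if op_id >= 4:
        out = np.flip(out, axis=-1)
    return out.copy()


def compose_augment(op_a: int, op_b: int) -> int:
    """Index of the dihedral op equivalent to applying op_a then op_b."""
    probe = np.arange(16.0).reshape(4, 4)
    target = augment(augment(probe, op_a), op_b)
    for op in range(N_AUGMENT_OPS):
        if np.array_equal(augment(probe, op), target):
            return op
    raise RuntimeError("dihedral composition not closed")  # pragma: no cover


def sample_patch_pair(lr: np.ndarray, hr: np.ndarray, s: int, size: int = 48,
                      rng: np.random.Generator | None = None,
                      aug: bool = True, provenance: dict | None = None) -> TrainSamplePair:
    """Aligned random LR/HR crop; the HR origin sits on the s-lattice."""
    rng = rng or np.random.default_rng(0)
    lh, lw = lr.shape
    if hr.shape != (s * lh, s * lw):
        raise ValueError(f"hr {hr.shape} is not {s}x the lr {lr.shape}")
    if lh < size or lw < size:
        raise ValueError(f"LR image {lr.shape} smaller than patch size {size}")
    oy = int(rng.integers(0, lh - size + 1))
    ox = int(rng.integers(0, lw - size + 1))
    op = int(rng.integers(0, N_AUGMENT_OPS)) if aug else 0
    lr_patch = augment(lr[oy:oy + size, ox:ox + size], op)
    hr_patch = augment(hr[s * oy:s * (oy + size), s * ox:s * (ox + size)], op)
    prov = dict(provenance or {})
    prov.update({"origin": (oy, ox), "aug": op, "scale": s})
    return TrainSamplePair(lr_patch=lr_patch, hr_patch=hr_patch, scale=s, provenance=prov)


def make_sequence_samples(vol: VolumeRecord, seq_len: int = 7) -> list:
    """One centered SliceSequence per full sliding window along depth."""
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    depth = vol.depth
    if depth < seq_len:
        warnings.warn(f"volume depth {depth} < sequence length {seq_len}; no samples")
        return []
    half = (seq_len - 1) // 2
    extra = seq_len - 1 - half
    out = []
    for t in range(extra, depth - half):
        out.append(SliceSequence.from_volume(vol.voxels, t, seq_len))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path) -> VolumeRecord:
    """Read a NIfTI volume or a directory of PNG slices; normalize to [0, 1]."""
    path = Path(path)
    if path.is_dir():
        from PIL import Image

        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG slices in {path}")
        slices = [np.asarray(Image.open(f).convert("L"), dtype=np.float64) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        vox = np.stack(slices, axis=2) / 255.0
        return VolumeRecord(voxels=normalize_intensities(vox), source_id=path.name)
    import nibabel as nib

    img = nib.load(str(path))
    vox = np.asarray(img.dataobj, dtype=np.float64)
    if vox.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {vox.shape}")
    return VolumeRecord(voxels=normalize_intensities(vox), source_id=path.stem,
                        spacing=tuple(float(z) for z in img.header.get_zooms()[:3]))


def write_volume(rec: VolumeRecord, path) -> None:
    """Write float32 NIfTI (.nii) or a directory of 8-bit PNG slices."""
    path = Path(path)
    if path.suffix in (".nii", ".gz") or str(path).endswith(".nii.gz"):
        import nibabel as nib

        img = nib.Nifti1Image(rec.voxels.astype(np.float32), affine=np.eye(4))
        nib.save(img, str(path))
        return
    from PIL import Image

    path.mkdir(parents=True, exist_ok=True)
    for i in range(rec.depth):
        arr = np.clip(rec.voxels[:, :, i] * 255.0, 0, 255).round().astype(np.uint8)
        Image.fromarray(arr, mode="L").save(path / f"slice_{i:04d}.png")
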