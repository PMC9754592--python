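"""Seedable MR-like 3D phantom generator.

Volumes are sums of randomly posed 3D ellipsoids drawn from a handful of
intensity classes (mimicking tissue-contrast diversity), smoothed in-plane
and optionally corrupted by Gaussian or Rician noise.  Because the ellipsoids
are three-dimensional, adjacent slices are strongly correlated and the
correlation decays with slice distance — the statistical structure the
sequence network exploits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .degradation_data import VolumeRecord, write_volume

__all__ = ["PhantomParams", "generate_volume", "generate_dataset"]


@dataclass(frozen=True)
class PhantomParams:
    height: int = 96
    width: int = 96
    depth: int = 16
    n_structures: int = 12
    intensity_classes: tuple = (0.25, 0.45, 0.65, 0.85)
    smoothness: float = 1.5   # in-plane Gaussian blur radius (pixels)
    noise_sd: float = 0.01
    noise_model: str = "gaussian"  # gaussian | rician
    seed: int = 0

    def __post_init__(self):
        if min(self.height, self.width, self.depth) < 16:
            raise ValueError("all dims must be >= 16")
        if self.n_structures < 0 or self.noise_sd < 0:
            raise ValueError("n_structures and noise_sd must be non-negative")
        if not all(0 < c < 1 for c in self.intensity_classes):
            raise ValueError("intensity classes must lie in (0, 1)")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


def _ellipsoid_mask(shape, center, semi, rng):
    """Soft axis-aligned 3D ellipsoid indicator on the voxel grid."""
    h, w, d = shape
    yy = (np.arange(h)[:, None, None] - center[0]) / semi[0]
    xx = (np.arange(w)[None, :, None] - center[1]) / semi[1]
    zz = (np.arange(d)[None, None, :] - center[2]) / semi[2]
    return (yy ** 2 + xx ** 2 + zz ** 2) <= 1.0


def generate_volume(params: PhantomParams) -> VolumeRecord:
    """Fully seed-determined phantom volume in [0, 1]."""
    rng = np.random.default_rng(params.seed)
    h, w, d = params.height, params.width, params.depth
    vol = np.zeros((h, w, d))
    classes = np.asarray(params.intensity_classes)
    for _ in range(params.n_structures):
        center = rng.uniform([0.15 * h, 0.15 * w, 0.1 * d],
                             [0.85 * h, 0.85 * w, 0.9 * d])
        semi = rng.uniform([0.06 * h, 0.06 * w, 0.25 * d],
                           [0.25 * h, 0.25 * w, 0.75 * d])
        intensity = float(rng.choice(classes))
        mask = _ellipsoid_mask((h, w, d), center, semi, rng)
        vol[mask] += intensity
    if params.smoothness > 0 and params.n_structures > 0:
        vol = gaussian_filter(vol, sigma=(params.smoothness, params.smoothness, 0.0))
    if params.noise_sd > 0:
        if params.noise_model == "gaussian":
            vol = vol + rng.normal(0.0, params.noise_sd, size=vol.shape)
        else:  # Rician magnitude noise
            re = vol + rng.normal(0.0, params.noise_sd, size=vol.shape)
            im = rng.normal(0.0, params.noise_sd, size=vol.shape)
            vol = np.sqrt(re ** 2 + im ** 2)
    vol = np.clip(vol, 0.0, 1.0)
    return VolumeRecord(voxels=vol, source_id=f"phantom-{params.seed}")


def generate_dataset(n_volumes: int, params: PhantomParams, out_dir) -> dict:
    """Write ``n_volumes`` NIfTI phantoms plus a JSON manifest; seeds derive
    deterministically (and pairwise distinctly) from ``params.seed``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = [int(s.generate_state(1)[0])
             for s in np.random.SeedSequence(params.seed).spawn(n_volumes)]
    entries = []
    for i, seed in enumerate(seeds):
        p = PhantomParams(**{**asdict(params), "seed": seed,
                             "intensity_classes": tuple(params.intensity_classes)})
        rec = generate_volume(p)
        name = f"phantom_{i:03d}.nii"
        write_volume(rec, out_dir / name)
        entries.append({"id": rec.source_id, "file": name, "seed": seed})
    manifest = {"master_seed": params.seed, "params": asdict(params), "volumes": entries}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
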