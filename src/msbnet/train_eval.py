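"""Training loop, PSNR/SSIM metrics, checkpointing, and the ablation harness.

Evaluation follows the usual SR conventions: intensities in [0, 1] (PSNR peak
1.0, capped at 100 dB for identical inputs), SSIM with an 11-tap Gaussian
window (sigma 1.5, K1=0.01, K2=0.03), and a border of ``scale`` pixels
excluded from both metrics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity

from .arch_core import count_parameters
from .degradation_data import VolumeRecord, degrade_bicubic, sample_patch_pair
from .msbfan import (MSBFAN, MsbfanConfig, SebConcat, SliceSequence,
                     build_msbfan)
from .msbpn import MSBPN, ProjectionSpec, build_msbpn, msbpn_forward
from .nn import Adam, l1_loss
from .resize import bicubic_resize
from .synthetic_phantom import PhantomParams, generate_volume

__all__ = [
    "TrainConfig",
    "MetricResult",
    "psnr",
    "ssim",
    "lr_schedule",
    "train",
    "evaluate",
    "bicubic_upsample",
    "save_model",
    "load_model",
    "run_ablation",
    "ABLATION_GRIDS",
]

PSNR_CAP_DB = 100.0


@dataclass
class TrainConfig:
    loss: str = "L1"
    lr_init: float = 1e-4
    lr_decay_factor: float = 10.0
    total_epochs: int = 100
    decay_at: int | None = None  # default: total_epochs // 2
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    patch: int = 48
    batch_size: int = 8
    seed: int = 0
    max_steps: int | None = None  # stop early (reduced-scale runs)

    def __post_init__(self):
        if self.loss != "L1":
            raise ValueError("only L1 loss is supported")
        if self.decay_at is None:
            self.decay_at = self.total_epochs // 2


@dataclass
class MetricResult:
    psnr_db: float
    ssim: float
    n_images: int


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def psnr(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> float:
    """10*log10(peak^2 / MSE); identical inputs report the 100 dB cap."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP_DB
    return min(PSNR_CAP_DB, 10.0 * np.log10(peak ** 2 / mse))


def ssim(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> float:
    """Mean local SSIM, 11x11 Gaussian window sigma=1.5, K1=0.01, K2=0.03."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if min(a.shape) < 11:
        raise ValueError("images smaller than the 11x11 SSIM window")
    return float(structural_similarity(
        a, b, data_range=peak, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    if not 0 <= epoch < cfg.total_epochs:
        raise ValueError(f"epoch {epoch} outside 0..{cfg.total_epochs - 1}")
    if epoch < cfg.decay_at:
        return cfg.lr_init
    return cfg.lr_init / cfg.lr_decay_factor


def bicubic_upsample(lr: np.ndarray, scale: int) -> np.ndarray:
    h, w = lr.shape[-2:]
    return np.clip(bicubic_resize(np.asarray(lr, dtype=np.float64),
                                  h * scale, w * scale), 0.0, 1.0)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(model, dataset, cfg: TrainConfig, log_path=None) -> list:
    """Minimize L1 between SR output and HR reference; returns the step log.

    ``dataset`` holds either TrainSamplePair items (single-image models, which
    are mini-batched) or ``(SliceSequence, hr_target)`` tuples (sequence
    models, consumed one at a time).
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr_init, beta1=cfg.adam_beta1,
               beta2=cfg.adam_beta2, eps=cfg.adam_eps)
    sequence_mode = isinstance(dataset[0], tuple)
    log = []
    step = 0
    fh = open(log_path, "w") if log_path else None
    try:
        for epoch in range(cfg.total_epochs):
            opt.lr = lr_schedule(epoch, cfg)
            order = rng.permutation(len(dataset))
            batch = 1 if sequence_mode else cfg.batch_size
            for start in range(0, len(order), batch):
                idx = order[start:start + batch]
                if sequence_mode:
                    seq, hr = dataset[idx[0]]
                    pred = model(seq)
                    target = np.asarray(hr, dtype=np.float64)[None, None]
                else:
                    items = [dataset[i] for i in idx]
                    x = np.stack([it.lr_patch for it in items])[:, None]
                    target = np.stack([it.hr_patch for it in items])[:, None]
                    pred = model(x)
                loss, grad = l1_loss(pred, target)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss {loss} at epoch {epoch} step {step}; "
                        "lower the learning rate or check the data range")
                model.zero_grad()
                model.backward(grad)
                opt.step()
                entry = {"epoch": epoch, "step": step, "loss": loss, "lr": opt.lr}
                log.append(entry)
                if fh:
                    fh.write(json.dumps(entry) + "\n")
                step += 1
                if cfg.max_steps is not None and step >= cfg.max_steps:
                    return log
    finally:
        if fh:
            fh.close()
    return log


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(model, path) -> None:
    """Self-describing checkpoint: weights + enough config to rebuild."""
    if isinstance(model, MSBPN):
        meta = {"kind": "msbpn", "config": {
            "task_scale": model.spec.task_scale, "scales": list(model.spec.scales),
            "m": model.spec.m, "n": model.spec.n, "dense": model.spec.dense,
            "channels": model.spec.channels, "single_scale": model.spec.single_scale}}
    elif isinstance(model, (MSBFAN, SebConcat)):
        meta = {"kind": "seb_concat" if isinstance(model, SebConcat) else "msbfan",
                "config": asdict(model.cfg)}
    else:
        raise TypeError(f"cannot checkpoint {type(model).__name__}")
    state = {f"param::{k}": v for k, v in model.state_dict().items()}
    state["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_model(path):
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        state = {k[len("param::"):]: data[k] for k in data.files
                 if k.startswith("param::")}
    cfg = meta["config"]
    if meta["kind"] == "msbpn":
        cfg["scales"] = tuple(cfg["scales"])
        model = build_msbpn(ProjectionSpec(**cfg))
    else:
        if cfg.get("offsets") is not None:
            cfg["offsets"] = tuple(cfg["offsets"])
        mcfg = MsbfanConfig(**cfg)
        model = SebConcat(mcfg) if meta["kind"] == "seb_concat" else build_msbfan(mcfg)
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def _sr_slice(model, lr_seq_or_img, scale):
    if isinstance(model, MSBPN):
        return msbpn_forward(lr_seq_or_img, model)
    return model.sr(lr_seq_or_img)


def evaluate(model, volumes, scale: int, border: int | None = None,
             max_slices: int | None = None) -> MetricResult:
    """Per-slice SR vs HR ground truth, border-cropped and averaged."""
    border = scale if border is None else border
    psnrs, ssims = [], []
    for vol in volumes:
        vox = vol.voxels if isinstance(vol, VolumeRecord) else np.asarray(vol)
        lr_vox = np.stack([degrade_bicubic(vox[:, :, i], scale)
                           for i in range(vox.shape[2])], axis=2)
        n = vox.shape[2] if max_slices is None else min(max_slices, vox.shape[2])
        for i in range(n):
            hr = vox[:, :, i]
            if isinstance(model, MSBPN):
                sr = _sr_slice(model, lr_vox[:, :, i], scale)
            else:
                seq = (SliceSequence.from_volume_offsets(lr_vox, i, model.offsets)
                       if isinstance(model, MSBFAN)
                       else SliceSequence.from_volume(lr_vox, i, model.cfg.seq_len))
                sr = model.sr(seq)
            sr = np.clip(sr, 0.0, 1.0)
            b = border
            hr_c, sr_c = (hr[b:-b, b:-b], sr[b:-b, b:-b]) if b else (hr, sr)
            psnrs.append(psnr(sr_c, hr_c))
            ssims.append(ssim(sr_c, hr_c))
    return MetricResult(psnr_db=float(np.mean(psnrs)), ssim=float(np.mean(ssims)),
                        n_images=len(psnrs))


def reduced_scale_learning_check(seed: int, scale: int = 2, channels: int = 16,
                                 steps: int = 300, patch: int = 16,
                                 n_eval_slices: int = 10) -> dict:
    """Train a tiny MSBPN on seeded phantoms and compare with plain bicubic.

    Returns {"model_psnr", "bicubic_psnr", "beats_bicubic"} for one seed.
    """
    rng = np.random.default_rng(seed)
    vols = [generate_volume(PhantomParams(height=96, width=96, depth=16,
                                          seed=seed * 100 + i)) for i in range(3)]
    train_vols, heldout = vols[:2], vols[2]
    dataset = []
    for vol in train_vols:
        for i in range(vol.voxels.shape[2]):
            hr = vol.voxels[:, :, i]
            lr = degrade_bicubic(hr, scale)
            for _ in range(4):
                dataset.append(sample_patch_pair(lr, hr, scale, size=patch, rng=rng))
    model = build_msbpn(ProjectionSpec(task_scale=scale, m=1, n=1,
                                       channels=channels), seed=seed)
    train(model, dataset, TrainConfig(total_epochs=max(1, steps), batch_size=4,
                                      seed=seed, max_steps=steps))
    res = evaluate(model, [heldout], scale, max_slices=n_eval_slices)
    b = scale
    bic = []
    for i in range(n_eval_slices):
        hr = heldout.voxels[:, :, i]
        up = bicubic_upsample(degrade_bicubic(hr, scale), scale)
        bic.append(psnr(up[b:-b, b:-b], hr[b:-b, b:-b]))
    bic_mean = float(np.mean(bic))
    return {"model_psnr": res.psnr_db, "bicubic_psnr": bic_mean,
            "beats_bicubic": bool(res.psnr_db > bic_mean)}


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------

ABLATION_GRIDS = ("dense", "multiscale", "baselines", "slice_order",
                  "slice_length", "fusion")


def _tiny_volumes(n, seed, height=48, width=48, depth=16):
    params = PhantomParams(height=height, width=width, depth=depth,
                           n_structures=6, smoothness=1.0, noise_sd=0.01, seed=seed)
    seeds = [int(s.generate_state(1)[0])
             for s in np.random.SeedSequence(seed).spawn(n)]
    return [generate_volume(PhantomParams(**{**asdict(params), "seed": s}))
            for s in seeds]


def _train_and_eval(model, scale, steps, seed, volumes, patch=12):
    """Reduced-scale training for ablation rows; returns (psnr, ssim)."""
    if steps <= 0:
        return None, None
    rng = np.random.default_rng(seed)
    if isinstance(model, MSBPN):
        dataset = []
        for vol in volumes[:-1]:
            for i in range(vol.voxels.shape[2]):
                hr = vol.voxels[:, :, i]
                lr = degrade_bicubic(hr, scale)
                dataset.append(sample_patch_pair(lr, hr, scale, size=patch, rng=rng))
    else:
        dataset = []
        seq_source = (lambda lrv, i: SliceSequence.from_volume_offsets(lrv, i, model.offsets)
                      if isinstance(model, MSBFAN)
                      else SliceSequence.from_volume(lrv, i, model.cfg.seq_len))
        for vol in volumes[:-1]:
            vox = vol.voxels
            lr_vox = np.stack([degrade_bicubic(vox[:, :, i], scale)
                               for i in range(vox.shape[2])], axis=2)
            for i in range(vox.shape[2]):
                dataset.append((seq_source(lr_vox, i), vox[:, :, i]))
    cfg = TrainConfig(total_epochs=max(1, steps), batch_size=4, seed=seed,
                      max_steps=steps)
    train(model, dataset, cfg)
    res = evaluate(model, volumes[-1:], scale, max_slices=4)
    return res.psnr_db, res.ssim


def run_ablation(grid_name: str, scale: int = 4, channels: int = 8,
                 seq_len: int = 3, steps: int = 0, seed: int = 0) -> dict:
    """Build (and optionally train at reduced scale) one ablation grid.

    Emits the corresponding table structure with per-variant parameter counts;
    absolute PSNR/SSIM values are meaningful only relative to each other and
    only when ``steps`` > 0.
    """
    if grid_name not in ABLATION_GRIDS:
        raise ValueError(f"unknown grid {grid_name!r}; choose from {ABLATION_GRIDS}")
    volumes = _tiny_volumes(3, seed) if steps > 0 else []
    rows = []

    def finish(variant, model, **extra):
        report = count_parameters(model)
        p, s = _train_and_eval(model, scale, steps, seed, volumes)
        rows.append({"variant": variant, "params": report.total_params,
                     "params_K": report.params_K, "psnr": p, "ssim": s, **extra})

    if grid_name == "dense":
        for n in (1, 2, 3):
            for dense in (True, False):
                spec = ProjectionSpec(task_scale=scale, m=1, n=n,
                                      channels=channels, dense=dense)
                finish(f"M_m1_n{n}_{'w' if dense else 'wo'}_dense",
                       build_msbpn(spec, seed), n=n, dense=dense)
    elif grid_name == "multiscale":
        for n in (1, 2, 3):
            for single in (False, True):
                spec = ProjectionSpec(task_scale=scale, m=1, n=n,
                                      channels=channels, single_scale=single)
                finish(f"M_m1_n{n}_{'wo' if single else 'w'}_multiscale",
                       build_msbpn(spec, seed), n=n, multiscale=not single)
    elif grid_name == "baselines":
        base = dict(task_scale=scale, seq_len=seq_len, channels=channels,
                    teb_blocks=2, attention_reduction=4)
        finish("seb_1slice", build_msbfan(
            MsbfanConfig(**{**base, "seq_len": 1}), seed))
        finish("seb_concat", SebConcat(MsbfanConfig(**base), seed))
        finish("forward_only", build_msbfan(
            MsbfanConfig(**{**base, "mode": "forward"}), seed))
        finish("backward_only", build_msbfan(
            MsbfanConfig(**{**base, "mode": "backward"}), seed))
        finish("full", build_msbfan(MsbfanConfig(**base), seed))
    elif grid_name == "slice_order":
        orders = {"P": (-1, -2), "F": (1, 2), "PF": (-1, 1)}
        base = dict(task_scale=scale, channels=channels, teb_blocks=2,
                    attention_reduction=4, seq_len=3)
        for train_name, train_offsets in orders.items():
            model = build_msbfan(
                MsbfanConfig(**{**base, "offsets": train_offsets}), seed)
            report = count_parameters(model)
            cell = {"variant": f"train_{train_name}", "params": report.total_params,
                    "params_K": report.params_K}
            if steps > 0:
                _train_and_eval(model, scale, steps, seed, volumes)
            for test_name, test_offsets in orders.items():
                if steps > 0:
                    test_model = build_msbfan(
                        MsbfanConfig(**{**base, "offsets": test_offsets}), seed)
                    test_model.load_state_dict(model.state_dict())
                    res = evaluate(test_model, volumes[-1:], scale, max_slices=4)
                    cell[f"test_{test_name}"] = {"psnr": res.psnr_db,
                                                 "ssim": res.ssim}
                else:
                    cell[f"test_{test_name}"] = {"psnr": None, "ssim": None}
            rows.append(cell)
    elif grid_name == "slice_length":
        for length in (1, 2, 3, 4):
            cfg = MsbfanConfig(task_scale=scale, seq_len=length, channels=channels,
                               teb_blocks=2, attention_reduction=4)
            finish(f"len_{length}", build_msbfan(cfg, seed), seq_len=length,
                   recon_slots=cfg.recon_slots)
    elif grid_name == "fusion":
        base = dict(task_scale=scale, seq_len=seq_len, channels=channels,
                    teb_blocks=2, attention_reduction=4, dbpn_stages=2)
        for variant, kw in [("msbpn_attention", {}),
                            ("dbpn_attention", {"seb_kind": "dbpn"}),
                            ("msbpn_residual", {"fusion": "residual"}),
                            ("dbpn_residual", {"seb_kind": "dbpn",
                                               "fusion": "residual"})]:
            finish(variant, build_msbfan(MsbfanConfig(**{**base, **kw}), seed), **kw)

    return {"grid": grid_name, "scale": scale, "channels": channels,
            "steps": steps, "rows": rows}
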