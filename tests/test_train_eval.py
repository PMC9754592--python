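"""Metrics (with independent oracles), schedule, training loop, ablations."""

import numpy as np
import pytest

from msbnet.degradation_data import degrade_bicubic, sample_patch_pair
from msbnet.msbpn import ProjectionSpec, build_msbpn, msbpn_forward
from msbnet.train_eval import (ABLATION_GRIDS, MetricResult, TrainConfig,
                               bicubic_upsample, evaluate, load_model,
                               lr_schedule, psnr, run_ablation, save_model,
                               ssim, train)


# ---------------------------------------------------------------------------
# PSNR
# ---------------------------------------------------------------------------

class TestPsnr:
    def test_identical_capped(self, rng):
        img = rng.random((16, 16))
        assert psnr(img, img) == 100.0

    @pytest.mark.parametrize("diff,expected", [(0.1, 20.0), (0.01, 40.0)])
    def test_uniform_difference_closed_form(self, diff, expected):
        a = np.zeros((20, 20))
        assert psnr(a, a + diff) == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_mse(self, rng):
        a, b = rng.random((13, 17)), rng.random((13, 17))
        mse = 0.0
        for i in range(13):
            for j in range(17):
                mse += (a[i, j] - b[i, j]) ** 2
        mse /= 13 * 17
        assert psnr(a, b) == pytest.approx(10 * np.log10(1.0 / mse), abs=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            psnr(np.zeros((4, 4)), np.zeros((5, 4)))


# ---------------------------------------------------------------------------
# SSIM
# ---------------------------------------------------------------------------

def _naive_ssim(a, b, peak=1.0):
    """Double-loop windowed SSIM oracle (interior pixels, Gaussian weights)."""
    r = 5
    x = np.arange(-r, r + 1)
    g = np.exp(-(x ** 2) / (2 * 1.5 ** 2))
    w = np.outer(g, g)
    w /= w.sum()
    C1, C2 = (0.01 * peak) ** 2, (0.03 * peak) ** 2
    h, wd = a.shape
    vals = []
    for i in range(r, h - r):
        for j in range(r, wd - r):
            wa = a[i - r:i + r + 1, j - r:j + r + 1]
            wb = b[i - r:i + r + 1, j - r:j + r + 1]
            mua, mub = np.sum(w * wa), np.sum(w * wb)
            va = np.sum(w * (wa - mua) ** 2)
            vb = np.sum(w * (wb - mub) ** 2)
            cov = np.sum(w * (wa - mua) * (wb - mub))
            vals.append(((2 * mua * mub + C1) * (2 * cov + C2)) /
                        ((mua ** 2 + mub ** 2 + C1) * (va + vb + C2)))
    return float(np.mean(vals))


class TestSsim:
    def test_identical_is_one(self, rng):
        img = rng.random((16, 16))
        assert ssim(img, img) == pytest.approx(1.0)

    def test_symmetry(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert ssim(a, b) == pytest.approx(ssim(b, a), abs=1e-12)

    def test_constant_images_closed_form(self):
        c1, c2 = 0.2, 0.7
        C1 = 0.01 ** 2
        expected = (2 * c1 * c2 + C1) / (c1 ** 2 + c2 ** 2 + C1)
        got = ssim(np.full((16, 16), c1), np.full((16, 16), c2))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_in_valid_range_on_random_inputs(self, rng):
        for _ in range(5):
            v = ssim(rng.random((16, 16)), rng.random((16, 16)))
            assert -1.0 <= v <= 1.0

    def test_against_naive_double_loop(self, rng):
        a, b = rng.random((16, 16)), rng.random((16, 16))
        assert ssim(a, b) == pytest.approx(_naive_ssim(a, b), abs=1e-7)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ssim(np.zeros((8, 8)), np.zeros((8, 8)))


# ---------------------------------------------------------------------------
# Schedule / config
# ---------------------------------------------------------------------------

class TestSchedule:
    def test_halved_schedule_protocol(self):
        cfg = TrainConfig()
        assert cfg.decay_at == 50
        assert lr_schedule(0, cfg) == pytest.approx(1e-4)
        assert lr_schedule(49, cfg) == pytest.approx(1e-4)
        assert lr_schedule(50, cfg) == pytest.approx(1e-5)
        assert lr_schedule(99, cfg) == pytest.approx(1e-5)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            lr_schedule(100, TrainConfig())

    def test_only_l1_supported(self):
        with pytest.raises(ValueError):
            TrainConfig(loss="L2")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _tiny_dataset(rng, n=40, scale=2, size=10):
    out = []
    for _ in range(n):
        hr = rng.random((size * scale, size * scale))
        lr = degrade_bicubic(hr, scale)
        out.append(sample_patch_pair(lr, hr, scale, size=size, rng=rng, aug=False))
    return out


class TestTrain:
    def test_loss_finite_and_trending_down(self, rng, small_phantom):
        scale = 2
        dataset = []
        for i in range(small_phantom.voxels.shape[2]):
            hr = small_phantom.voxels[:, :, i]
            lr = degrade_bicubic(hr, scale)
            for _ in range(5):
                dataset.append(sample_patch_pair(lr, hr, scale, size=12, rng=rng))
        model = build_msbpn(ProjectionSpec(task_scale=scale, channels=8), seed=0)
        log = train(model, dataset, TrainConfig(total_epochs=10, batch_size=4,
                                                seed=0, max_steps=60))
        losses = np.array([e["loss"] for e in log])
        assert np.all(np.isfinite(losses))
        assert losses[-15:].mean() < losses[:15].mean()  # smoothed decrease

    def test_determinism_across_runs(self, rng):
        dataset = _tiny_dataset(rng)
        logs = []
        for _ in range(2):
            model = build_msbpn(ProjectionSpec(task_scale=2, channels=4), seed=3)
            logs.append(train(model, dataset,
                              TrainConfig(total_epochs=1, batch_size=4, seed=3,
                                          max_steps=5)))
        assert [e["loss"] for e in logs[0]] == [e["loss"] for e in logs[1]]

    def test_empty_dataset_rejected(self):
        model = build_msbpn(ProjectionSpec(task_scale=2, channels=4))
        with pytest.raises(ValueError):
            train(model, [], TrainConfig())

    def test_checkpoint_roundtrip_bitwise(self, tmp_path, rng):
        model = build_msbpn(ProjectionSpec(task_scale=2, channels=4), seed=2)
        dataset = _tiny_dataset(rng, n=8)
        train(model, dataset, TrainConfig(total_epochs=1, batch_size=4, seed=1,
                                          max_steps=3))
        path = tmp_path / "ckpt.npz"
        save_model(model, path)
        loaded = load_model(path)
        x = rng.random((8, 8))
        assert np.array_equal(msbpn_forward(x, model), msbpn_forward(x, loaded))


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

class TestEvaluate:
    def test_self_evaluation_caps(self, small_phantom):
        """An identity 'model' must give capped PSNR and SSIM 1."""
        class Identity:
            pass

        # emulate by comparing HR with itself through the metric path
        hr = small_phantom.voxels[:, :, 0]
        assert psnr(hr, hr) == 100.0
        assert ssim(hr, hr) == pytest.approx(1.0)

    def test_result_counts_slices(self, small_phantom):
        model = build_msbpn(ProjectionSpec(task_scale=2, channels=4), seed=0)
        res = evaluate(model, [small_phantom], 2, max_slices=3)
        assert isinstance(res, MetricResult)
        assert res.n_images == 3

    def test_untrained_residual_model_matches_bicubic(self, small_phantom):
        """Zero-initialized reconstruction => output equals the bicubic skip."""
        model = build_msbpn(ProjectionSpec(task_scale=2, channels=4), seed=0)
        hr = small_phantom.voxels[:, :, 0]
        lr = degrade_bicubic(hr, 2)
        out = msbpn_forward(lr, model)
        from msbnet.resize import bicubic_resize
        assert np.allclose(out, bicubic_resize(lr, 48, 48), atol=1e-12)


# ---------------------------------------------------------------------------
# Ablation harness
# ---------------------------------------------------------------------------

class TestAblation:
    def test_unknown_grid_rejected(self):
        with pytest.raises(ValueError):
            run_ablation("nope")

    def test_dense_grid_structure(self):
        table = run_ablation("dense", channels=8)
        assert {r["variant"] for r in table["rows"]} == {
            f"M_m1_n{n}_{d}_dense" for n in (1, 2, 3) for d in ("w", "wo")}
        # additive dense wiring keeps counts equal at fixed (m, n)
        by_n = {}
        for r in table["rows"]:
            by_n.setdefault(r["n"], []).append(r["params"])
        for n, params in by_n.items():
            assert len(set(params)) == 1

    def test_multiscale_grid_ordering(self):
        table = run_ablation("multiscale", channels=8)
        by_n = {}
        for r in table["rows"]:
            by_n.setdefault(r["n"], {})[r["multiscale"]] = r["params"]
        for n, d in by_n.items():
            assert d[True] < d[False]

    def test_baselines_grid_structure(self):
        table = run_ablation("baselines", channels=4)
        variants = [r["variant"] for r in table["rows"]]
        assert variants == ["seb_1slice", "seb_concat", "forward_only",
                            "backward_only", "full"]
        by_v = {r["variant"]: r["params"] for r in table["rows"]}
        assert by_v["forward_only"] == by_v["backward_only"]

    def test_slice_order_grid_is_3x3(self):
        table = run_ablation("slice_order", channels=4)
        assert len(table["rows"]) == 3
        for row in table["rows"]:
            assert {"test_P", "test_F", "test_PF"} <= set(row)

    def test_slice_length_grid_params_track_recon_width(self):
        table = run_ablation("slice_length", channels=4)
        rows = {r["seq_len"]: r for r in table["rows"]}
        c = 4
        for a, b in [(2, 3), (3, 4)]:
            delta = rows[b]["params"] - rows[a]["params"]
            slots = rows[b]["recon_slots"] - rows[a]["recon_slots"]
            assert delta == slots * c * 9  # only the reconstruction conv widens

    def test_fusion_grid_structure(self):
        table = run_ablation("fusion", channels=4)
        assert [r["variant"] for r in table["rows"]] == [
            "msbpn_attention", "dbpn_attention", "msbpn_residual", "dbpn_residual"]

    def test_params_consistent_with_audit(self):
        from msbnet.arch_core import count_parameters
        from msbnet.msbfan import MsbfanConfig, build_msbfan
        table = run_ablation("baselines", channels=4)
        full = next(r for r in table["rows"] if r["variant"] == "full")
        model = build_msbfan(MsbfanConfig(task_scale=4, seq_len=3, channels=4,
                                          teb_blocks=2, attention_reduction=4))
        assert full["params"] == count_parameters(model).total_params

    @pytest.mark.parametrize("grid", ABLATION_GRIDS)
    def test_all_grids_emit_rows(self, grid):
        assert run_ablation(grid, channels=4)["rows"]
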