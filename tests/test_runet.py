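"""Detection network: architecture contracts, loss definition, training loop."""

import numpy as np
import pytest

from holomass.nn import Tensor
from holomass.optics import OpticalConfig
from holomass.runet import (
    MapCodec,
    RUNetConfig,
    TrainConfig,
    build_runet,
    load_runet,
    predict_maps,
    runet_loss,
    save_runet,
    train_runet,
)
from holomass.simulate import (
    SceneParams,
    TruthMaps,
    render_truth_maps,
    sample_runet_scene,
    simulate_hologram,
)

TINY = RUNetConfig(
    down_filters=(4, 6, 8, 8),
    up_filters=(8, 6, 4, 4),
    convs_per_block=1,
    input_shape=(32, 32),
)


def tiny_stream(seed, n_particles=(1, 2)):
    cfg = OpticalConfig()
    params = SceneParams(
        image_shape=(32, 32), n_particles=n_particles, z_range_um=(400, 800),
        margin_px=4.0,
    )
    rng = np.random.default_rng(seed)
    while True:
        scene = sample_runet_scene(rng, cfg, params)
        holo = simulate_hologram(scene, rng_seed=int(rng.integers(0, 2**31 - 1)))
        yield holo, render_truth_maps(scene)


class TestArchitecture:
    def test_output_shape_and_ranges(self):
        model = build_runet(TINY, seed=0)
        x = np.random.default_rng(0).normal(size=(2, 32, 32, 1)).astype(np.float32)
        out = model.forward(x).data
        assert out.shape == (2, 32, 32, 5)
        assert np.all(np.isfinite(out))
        assert np.all((out[..., 0] > 0) & (out[..., 0] < 1))  # sigmoid arm
        assert np.all(out[..., 1:] >= 0)  # ReLU arm

    def test_indivisible_input_shape_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            RUNetConfig(input_shape=(100, 100))
        model = build_runet(TINY, seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 30, 30, 1), dtype=np.float32))

    def test_parameter_count_is_function_of_config(self):
        n1 = sum(p.data.size for p in build_runet(TINY, seed=0).parameters())
        n2 = sum(p.data.size for p in build_runet(TINY, seed=99).parameters())
        assert n1 == n2 == 6827

    def test_default_config_parameter_count(self):
        n = sum(p.data.size for p in build_runet(RUNetConfig(), seed=0).parameters())
        assert n == 975501


class TestLoss:
    def _truth(self, seg, z, mass, dx, dy, mask):
        return TruthMaps(seg, z, mass, dx, dy, mask)

    def test_zero_regression_at_truth(self):
        codec = MapCodec()
        rng = np.random.default_rng(0)
        seg = (rng.uniform(size=(8, 8)) > 0.7).astype(float)
        truth = self._truth(
            seg,
            seg * 900.0,
            seg * 50.0,
            np.clip(rng.normal(size=(8, 8)) * 4, -16, 16),
            np.clip(rng.normal(size=(8, 8)) * 4, -16, 16),
            np.ones((8, 8), dtype=bool),
        )
        target, mask = codec.encode_targets(truth)
        pred = Tensor(target[None])
        loss = runet_loss(pred, target[None], mask[None])
        seg_only = runet_loss(
            pred, target[None], mask[None], {"z": 0, "mass": 0, "dx": 0, "dy": 0}
        )
        assert float(loss.data) == pytest.approx(float(seg_only.data))

    def test_all_background_reduces_to_seg_bce(self):
        target = np.zeros((1, 8, 8, 5), dtype=np.float32)
        mask = np.zeros_like(target)
        mask[..., 0] = 1.0
        pred_np = np.full((1, 8, 8, 5), 0.3, dtype=np.float32)
        loss = runet_loss(Tensor(pred_np), target, mask)
        expected = -np.log(1 - 0.3)  # pure background BCE
        assert float(loss.data) == pytest.approx(expected, rel=1e-5)

    def test_single_masked_pixel_unit_error(self):
        # a 4x4 map with one masked pixel off by 1 unit in the z channel
        target = np.zeros((1, 4, 4, 5), dtype=np.float32)
        mask = np.zeros_like(target)
        mask[0, 1, 2, 1] = 1.0
        mask[0, 3, 3, 1] = 1.0  # 2 masked pixels
        pred_np = target.copy()
        pred_np[0, 1, 2, 1] = 1.0
        w = {"seg": 0.0, "z": 2.0, "mass": 0.0, "dx": 0.0, "dy": 0.0}
        loss = runet_loss(Tensor(pred_np), target, mask, w)
        assert float(loss.data) == pytest.approx(2.0 * 1.0 / 2, rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            runet_loss(
                Tensor(np.zeros((1, 4, 4, 5))),
                np.zeros((1, 8, 8, 5)),
                np.zeros((1, 8, 8, 5)),
            )

    def test_loss_permutation_invariant_over_pixels(self):
        rng = np.random.default_rng(3)
        target = rng.uniform(0.1, 0.9, size=(1, 4, 4, 5)).astype(np.float32)
        mask = np.ones_like(target)
        pred_np = rng.uniform(0.1, 0.9, size=(1, 4, 4, 5)).astype(np.float32)
        base = float(runet_loss(Tensor(pred_np), target, mask).data)
        perm = rng.permutation(16)
        p2 = pred_np.reshape(1, 16, 5)[:, perm].reshape(1, 4, 4, 5)
        t2 = target.reshape(1, 16, 5)[:, perm].reshape(1, 4, 4, 5)
        permuted = float(runet_loss(Tensor(p2), t2, mask).data)
        assert permuted == pytest.approx(base, rel=1e-6)


class TestTraining:
    CFG = TrainConfig(
        learning_rate=1e-3, batch_size=4, epochs=3, n_samples=24, prebuffer=12, seed=3
    )

    def test_loss_decreases_and_history_recorded(self):
        model = build_runet(TINY, seed=1)
        hist = train_runet(model, tiny_stream(5), self.CFG)
        assert len(hist["epoch_loss"]) == 3
        assert hist["smoothed_loss"][-1] < hist["epoch_loss"][0]

    def test_same_seed_identical_history(self):
        h1 = train_runet(build_runet(TINY, seed=1), tiny_stream(5), self.CFG)
        h2 = train_runet(build_runet(TINY, seed=1), tiny_stream(5), self.CFG)
        assert h1["epoch_loss"] == h2["epoch_loss"]

    def test_checkpoint_reload_bit_identical(self, tmp_path):
        model = build_runet(TINY, seed=1)
        codec = MapCodec()
        train_runet(model, tiny_stream(5), self.CFG, codec)
        path = tmp_path / "runet.npz"
        save_runet(path, model, codec, {"seed": 3})
        model2, codec2, meta = load_runet(path)
        assert codec2 == codec
        assert meta["provenance"]["seed"] == 3
        x = np.random.default_rng(0).normal(size=(1, 32, 32, 1)).astype(np.float32)
        assert np.array_equal(model.forward(x).data, model2.forward(x).data)


class TestPredictMaps:
    def test_output_is_decoded_and_shaped(self):
        model = build_runet(TINY, seed=0)
        codec = MapCodec()
        holo = np.ones((32, 32))
        maps = predict_maps(model, holo, codec)
        assert maps.shape == (32, 32, 5)
        # offsets decoded into the signed range
        assert maps[..., 3].min() >= -codec.offset_range - 1e-6

    def test_padding_for_indivisible_inputs(self):
        model = build_runet(TINY, seed=0)
        maps = predict_maps(model, np.ones((30, 30)), MapCodec())
        assert maps.shape == (30, 30, 5)

    def test_tiled_inference_matches_shape(self):
        model = build_runet(TINY, seed=0)
        maps = predict_maps(model, np.ones((48, 80)), MapCodec(), tile=32, overlap=16)
        assert maps.shape == (48, 80, 5)
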