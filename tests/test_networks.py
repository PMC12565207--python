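import numpy as np
import pytest

from lesionseg.io import MultiModalVolume
from lesionseg.networks import (
    MBConvSpec,
    NetworkSpec,
    build_mbconv3d,
    build_network,
    count_trainable_parameters,
    predict_patch,
    sliding_window_predict,
)
from lesionseg.nn.layers import Conv3d, Mode


@pytest.fixture(scope="module")
def tiny_model():
    return build_network(NetworkSpec.tiny(), seed=0)


class TestMBConvBlock:
    def test_stride_two_halves_spatial_dims(self):
        block = build_mbconv3d(MBConvSpec(4, 6, stride=2))
        out = block.forward(np.zeros((1, 4, 16, 16, 16), dtype=np.float32))
        assert out.shape == (1, 6, 8, 8, 8)

    def test_residual_flag_derivation(self):
        assert MBConvSpec(8, 8, stride=1).use_residual
        assert not MBConvSpec(8, 8, stride=2).use_residual
        assert not MBConvSpec(8, 12, stride=1).use_residual

    def test_zeroed_projection_passes_residual_identity(self):
        block = build_mbconv3d(MBConvSpec(4, 4, stride=1))
        proj = [l for l in block.body.layers if isinstance(l, Conv3d)][-1]
        proj.w.data[...] = 0
        x = np.random.default_rng(0).standard_normal((1, 4, 8, 8, 8)).astype(np.float32)
        out = block.forward(x)  # eval: BN uses init stats, beta 0 -> branch is 0
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_hand_counted_parameters(self):
        # expansion 1, 32 -> 48: depthwise 32*27 + BN 64 + projection 32*48 + BN 96
        block = build_mbconv3d(MBConvSpec(32, 48, stride=2))
        assert count_trainable_parameters(block) == 864 + 64 + 1536 + 96

    def test_gradient_flows_through_residual(self):
        block = build_mbconv3d(MBConvSpec(4, 4, stride=1))
        x = np.random.default_rng(1).standard_normal((2, 4, 8, 8, 8))
        out = block.forward(x, Mode(training=True))
        gx = block.backward(np.ones_like(out))
        assert np.all(np.isfinite(gx))
        assert np.abs(gx).max() > 0


class TestParameterCounts:
    def test_lone_pointwise_conv_with_bias(self):
        conv = Conv3d(1, 1, k=1, bias=True)
        assert count_trainable_parameters(conv) == 2

    def test_stem_conv_hand_count(self):
        conv = Conv3d(3, 32, k=3, bias=True)
        assert count_trainable_parameters(conv) == 3 * 32 * 27 + 32

    def test_efficientnet_within_printed_budget(self):
        model = build_network(NetworkSpec.efficientnet_default())
        assert count_trainable_parameters(model) <= 710_000

    def test_efficiency_ratio_over_baseline(self):
        small = count_trainable_parameters(build_network(NetworkSpec.efficientnet_default()))
        big = count_trainable_parameters(build_network(NetworkSpec.baseline_default()))
        assert small * 10 < big

    def test_alternate_baseline_reading_still_large(self):
        alt = count_trainable_parameters(build_network(NetworkSpec.baseline_text_341()))
        assert alt > 10_000_000


class TestForwardContracts:
    @pytest.mark.parametrize("variant", ["efficientnet3d_unet", "unet3d_baseline"])
    def test_shape_and_probability_range(self, variant):
        model = build_network(NetworkSpec.tiny(variant), seed=1)
        x = np.random.default_rng(0).standard_normal((1, 3, 32, 32, 32)).astype(np.float32)
        out = model.forward(x)
        assert out.shape == (1, 1, 32, 32, 32)
        assert np.all((out > 0) & (out < 1))

    def test_all_zero_input_finite(self, tiny_model):
        out = tiny_model.forward(np.zeros((1, 3, 16, 16, 16), dtype=np.float32))
        assert np.all(np.isfinite(out))

    def test_indivisible_spatial_dims_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="divisible"):
            tiny_model.forward(np.zeros((1, 3, 24, 24, 24), dtype=np.float32))

    def test_encoder_halves_resolution_at_each_stage(self, tiny_model):
        x = np.random.default_rng(2).standard_normal((1, 3, 32, 32, 32)).astype(np.float32)
        h = tiny_model.stem.forward(x)
        sizes = [h.shape[2]]
        for block in tiny_model.encoders:
            h = block.forward(h)
            sizes.append(h.shape[2])
        assert sizes == [32, 16, 8, 4, 2]

    def test_forward_nan_free_over_many_seeds(self):
        model = build_network(NetworkSpec.tiny(), seed=3)
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal((1, 3, 16, 16, 16))
            out = model.forward(x.astype(np.float32))
            assert np.all(np.isfinite(out)), f"NaN at seed {seed}"


class TestPredictPatch:
    def test_eval_mode_deterministic(self, tiny_model):
        x = np.random.default_rng(5).standard_normal((3, 16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(predict_patch(tiny_model, x),
                                      predict_patch(tiny_model, x))

    def test_random_init_mean_probability_sane(self):
        model = build_network(NetworkSpec.tiny(), seed=7)
        x = np.random.default_rng(8).standard_normal((3, 16, 16, 16)).astype(np.float32)
        assert 0.05 < predict_patch(model, x).mean() < 0.95


class _ConstantModel:
    """Stub emitting a constant probability field; spec-free test double."""

    def __init__(self, value):
        self.value = value

    def forward(self, x, mode=None):
        return np.full((x.shape[0], 1) + x.shape[2:], self.value)


class TestSlidingWindow:
    def _volume(self, shape=(40, 40, 40), seed=0):
        rng = np.random.default_rng(seed)
        return MultiModalVolume(rng.standard_normal((3, *shape)).astype(np.float32),
                                (1, 1, 1))

    def test_constant_network_gives_constant_field(self):
        pred = sliding_window_predict(_ConstantModel(0.37), self._volume(),
                                      patch_size=16, overlap=0.5)
        np.testing.assert_allclose(pred.probs, 0.37, atol=1e-12)
        assert pred.probs.shape == (40, 40, 40)

    def test_per_voxel_weights_average_to_one(self):
        # a unit-emitting network exposes any weight normalization defect
        pred = sliding_window_predict(_ConstantModel(1.0), self._volume(seed=1),
                                      patch_size=16, overlap=0.25)
        np.testing.assert_allclose(pred.probs, 1.0, atol=1e-12)

    def test_single_window_equals_predict_patch(self, tiny_model):
        volume = self._volume(shape=(16, 16, 16), seed=2)
        tiled = sliding_window_predict(tiny_model, volume, patch_size=16)
        direct = predict_patch(tiny_model, volume.channels)
        np.testing.assert_allclose(tiled.probs, direct, atol=1e-7)


class TestSpecSerialization:
    def test_round_trip(self):
        spec = NetworkSpec.baseline_default()
        assert NetworkSpec.from_dict(spec.to_dict()) == spec

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            NetworkSpec(variant="resnet3d")

    def test_checkpoint_round_trip_preserves_predictions(self, tmp_path, tiny_model):
        from lesionseg.training import Checkpoint

        ckpt = Checkpoint(spec=tiny_model.spec, state=tiny_model.state_dict(), seed=0)
        ckpt.save(tmp_path / "model")
        rebuilt = Checkpoint.load(tmp_path / "model").build()
        x = np.random.default_rng(3).standard_normal((3, 16, 16, 16)).astype(np.float32)
        np.testing.assert_allclose(predict_patch(rebuilt, x),
                                   predict_patch(tiny_model, x), atol=1e-7)
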