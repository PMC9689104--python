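"""Architecture contracts: atrous arithmetic, receptive fields, HAC
structure, encoder pyramid shapes, softmax output, weight transfer."""

import numpy as np
import pytest

from hrunet.model import (ENCODER_CHANNELS, HACSpec, ModelConfig,
                          atrous_conv_value, build_hac, build_hrunet,
                          encoder_state_dict, hac_placement_for_count,
                          load_model, load_pretrained_encoder, receptive_field,
                          save_encoder_weights, save_model)
from hrunet.nn import Conv2d

rng = np.random.default_rng(11)


class TestAtrousConvValue:
    def test_all_ones_rate1_counts_taps(self):
        grid = np.ones((7, 7))
        k = np.ones((3, 3))
        assert atrous_conv_value(grid, (3, 3), k, rate=1) == pytest.approx(9.0)

    def test_all_ones_rate2_counts_taps(self):
        grid = np.ones((5, 5))
        k = np.ones((3, 3))
        assert atrous_conv_value(grid, (2, 2), k, rate=2) == pytest.approx(9.0)

    def test_zero_grid(self):
        assert atrous_conv_value(np.zeros((5, 5)), (2, 2),
                                 rng.standard_normal((3, 3)), 1) == 0.0

    def test_rate1_equals_brute_force_standard_conv(self):
        """Exhaustive tap-summation oracle on random 7x7 grids."""
        for _ in range(5):
            grid = rng.standard_normal((7, 7))
            k = rng.standard_normal((3, 3))
            for m in range(7):
                for n in range(7):
                    want = 0.0
                    for di in (-1, 0, 1):
                        for dj in (-1, 0, 1):
                            if 0 <= m + di < 7 and 0 <= n + dj < 7:
                                want += grid[m + di, n + dj] * k[di + 1, dj + 1]
                    got = atrous_conv_value(grid, (m, n), k, rate=1)
                    assert got == pytest.approx(want, abs=1e-10)

    def test_matches_conv2d_layer(self):
        """The scalar definition agrees with the vectorized Conv2d layer."""
        x = rng.standard_normal((1, 1, 9, 9)).astype(np.float32)
        for rate in (1, 2, 3):
            conv = Conv2d(1, 1, 3, dilation=rate, rng=np.random.default_rng(4))
            full = conv.forward(x)[0, 0]
            k = conv.weight.value[0, 0]
            for m, n in [(0, 0), (4, 4), (8, 3)]:
                assert atrous_conv_value(x[0, 0], (m, n), k, rate) == \
                    pytest.approx(float(full[m, n]), abs=1e-4)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            atrous_conv_value(np.ones((6, 6)), (2, 2), np.ones((4, 4)), 1)


def impulse_extent(rates, n=64):
    """Nonzero-output extent of a real dilated-conv cascade on an impulse."""
    x = np.zeros((1, 1, n, n), dtype=np.float32)
    x[0, 0, n // 2, n // 2] = 1.0
    for r in rates:
        conv = Conv2d(1, 1, 3, dilation=r)
        conv.weight.value[...] = 1.0  # positive taps: no cancellation
        x = conv.forward(x)
    nz = np.argwhere(x[0, 0] != 0)
    return int(nz[:, 0].max() - nz[:, 0].min() + 1)


class TestReceptiveField:
    def test_cascade_1_2_3_gives_13(self):
        assert receptive_field([3, 3, 3], [1, 2, 3]) == 13

    @pytest.mark.parametrize("kernels, rates, expect",
                             [([3], [1], 3), ([3], [2], 5), ([3, 3], [1, 2], 7)])
    def test_closed_form_small_cases(self, kernels, rates, expect):
        assert receptive_field(kernels, rates) == expect

    @pytest.mark.parametrize("rates", [[1], [1, 2], [1, 2, 3]])
    def test_closed_form_matches_impulse_response(self, rates):
        assert receptive_field([3] * len(rates), rates) == impulse_extent(rates)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            receptive_field([], [])


class TestHAC:
    def test_default_spec_branch_count(self):
        assert HACSpec().n_branches == 5  # 4 parallel + 1 cascade

    def test_cascade_receptive_field_13(self):
        assert HACSpec().cascade_receptive_field() == 13

    def test_shape_preserving(self):
        block = build_hac(HACSpec(), channels=6)
        x = rng.standard_normal((2, 6, 8, 8)).astype(np.float32)
        assert block.forward(x).shape == x.shape

    def test_empty_spec_rejected(self):
        with pytest.raises(ValueError):
            HACSpec(parallel_rates=(), cascade_rates=())

    def test_gradient_flows_through_all_branches(self):
        block = build_hac(HACSpec(parallel_rates=(1, 2), cascade_rates=(1, 2)),
                          channels=3)
        x = rng.standard_normal((1, 3, 6, 6)).astype(np.float32)
        y = block.forward(x, training=True)
        block.zero_grad()
        block.backward(np.ones_like(y))
        for name, p in block.named_params():
            assert np.abs(p.grad).sum() > 0, name


class TestModelConfig:
    def test_size_must_divide_32(self):
        with pytest.raises(ValueError):
            ModelConfig(in_height=100, in_width=96)

    def test_unknown_placement_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(hac_placement=("res9",))

    def test_roundtrip_dict(self):
        cfg = ModelConfig(in_height=64, in_width=96,
                          hac_placement=("res4", "input"), seed=5)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg

    def test_placement_for_count(self):
        assert hac_placement_for_count(0) == ()
        assert hac_placement_for_count(3) == ("res4", "res3", "res2")
        assert len(hac_placement_for_count(6)) == 6
        with pytest.raises(ValueError):
            hac_placement_for_count(7)


@pytest.fixture(scope="module")
def model64():
    return build_hrunet(ModelConfig(in_height=64, in_width=64, seed=0))


class TestHRUNet:

    def test_encoder_pyramid_table_contract(self, model64):
        """Spatial sizes and channel counts at every stage: raw features
        64/256/512/1024/2048 reduced to 32/64/96/128/128."""
        x = rng.random((1, 1, 64, 64), dtype=np.float32)
        raw = model64.encoder(x)
        for name, (pre, post) in ENCODER_CHANNELS.items():
            assert raw[name].shape[1] == pre, name
            red = model64.reducers[name]
            assert red.layers[0].weight.shape == (post, pre, 1, 1), name
        pyr = model64.encoder_features(x)
        assert pyr.conv_block.shape == (1, 32, 32, 32)
        assert pyr.res1.shape == (1, 64, 16, 16)
        assert pyr.res2.shape == (1, 96, 8, 8)
        assert pyr.res3.shape == (1, 128, 4, 4)
        assert pyr.res4.shape == (1, 128, 2, 2)

    def test_res4_reduction_2048_to_128(self, model64):
        assert model64.reducers["res4"].layers[0].weight.shape[:2] == (128, 2048)

    def test_output_resolution_and_softmax(self, model64):
        x = rng.random((2, 1, 64, 64), dtype=np.float32)
        prob = model64.predict_proba(x)
        assert prob.shape == (2, 2, 64, 64)
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-5)

    def test_large_input_resolution_preserved(self):
        """Forward at the clinical working size keeps full resolution."""
        model = build_hrunet(ModelConfig(in_height=320, in_width=512, seed=0))
        x = rng.random((1, 1, 320, 512), dtype=np.float32)
        prob = model.predict_proba(x)
        assert prob.shape == (1, 2, 320, 512)
        np.testing.assert_allclose(prob.sum(axis=1), 1.0, atol=1e-5)

    def test_indivisible_input_rejected(self, model64):
        with pytest.raises(ValueError):
            model64.forward(rng.random((1, 1, 60, 60), dtype=np.float32))

    @pytest.mark.parametrize("count", range(7))
    def test_hac_placement_sweep_builds_and_runs(self, count):
        """Counts 0 (plain RU-Net) through 6 all build and forward."""
        cfg = ModelConfig(in_height=32, in_width=32,
                          hac_placement=hac_placement_for_count(count), seed=0)
        model = build_hrunet(cfg)
        out = model.predict_proba(rng.random((1, 1, 32, 32), dtype=np.float32))
        assert out.shape == (1, 2, 32, 32)


class TestWeightTransfer:
    def test_grayscale_equals_explicit_3channel(self, tiny_model_config):
        model = build_hrunet(tiny_model_config)
        x1 = rng.random((1, 1, 32, 32), dtype=np.float32)
        x3 = np.repeat(x1, 3, axis=1)
        np.testing.assert_array_equal(model.predict_proba(x1),
                                      model.predict_proba(x3))

    def test_load_roundtrip_changes_outputs_to_source(self, tmp_path,
                                                      tiny_model_config):
        src = build_hrunet(tiny_model_config)
        path = tmp_path / "enc.npz"
        save_encoder_weights(src, path)
        dst = build_hrunet(ModelConfig(in_height=32, in_width=32, seed=99))
        load_pretrained_encoder(dst, path)
        x = rng.random((1, 1, 32, 32), dtype=np.float32)
        np.testing.assert_array_equal(dst.encoder(x)["res4"],
                                      src.encoder(x)["res4"])

    def test_absent_source_is_noop(self, tiny_model_config):
        model = build_hrunet(tiny_model_config)
        before = {n: p.value.copy() for n, p in model.named_params()}
        load_pretrained_encoder(model, None)
        after = dict(model.named_params())
        assert all(np.array_equal(before[n], after[n].value) for n in before)

    def test_shape_mismatch_lists_blocks(self, tiny_model_config):
        model = build_hrunet(tiny_model_config)
        state = encoder_state_dict(model)
        state["conv1.weight"] = np.zeros((64, 3, 3, 3), dtype=np.float32)
        del state["bn1.gamma"]
        with pytest.raises(ValueError) as exc:
            load_pretrained_encoder(model, state)
        msg = str(exc.value)
        assert "conv1.weight" in msg and "bn1.gamma" in msg

    def test_checkpoint_roundtrip(self, tmp_path, tiny_model_config):
        model = build_hrunet(tiny_model_config)
        x = rng.random((1, 1, 32, 32), dtype=np.float32)
        save_model(model, tmp_path / "m.npz")
        clone = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(model.predict_proba(x),
                                      clone.predict_proba(x))
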