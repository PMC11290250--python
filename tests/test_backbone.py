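"""SE blocks, residual assembly and ablation-flag construction."""

import itertools

import numpy as np
import pytest

from amsnet import (
    AMSNet,
    ModelConfig,
    SEBasicBlock,
    SEParams,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
    se_excite,
    se_squeeze,
)
from amsnet.nn.losses import softmax


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


class TestSeSqueeze:
    def test_small_example(self):
        f = np.array([[[1.0, 2.0], [3.0, 4.0]]])
        assert se_squeeze(f)[0] == 2.5

    def test_constant_channel(self):
        f = np.full((3, 5, 5), 0.0)
        f[1] = 0.7
        np.testing.assert_allclose(se_squeeze(f), [0.0, 0.7, 0.0])

    def test_matches_double_loop_oracle(self, rng):
        f = rng.normal(size=(5, 7, 7))
        want = np.zeros(5)
        for k in range(5):
            for i in range(7):
                for j in range(7):
                    want[k] += f[k, i, j]
        want /= 49
        np.testing.assert_allclose(se_squeeze(f), want, rtol=1e-12)

    def test_empty_extent_rejected(self):
        with pytest.raises(ValueError):
            se_squeeze(np.empty((2, 0, 3)))


class TestSeExcite:
    def test_zero_weights_give_half(self):
        p = SEParams(w1=np.zeros((2, 4)), w2=np.zeros((4, 2)))
        np.testing.assert_allclose(se_excite(np.ones(4), p), 0.5)

    def test_outputs_strictly_in_unit_interval(self, rng):
        p = SEParams(w1=rng.normal(size=(2, 4)), w2=rng.normal(size=(4, 2)))
        ex = se_excite(rng.normal(size=4) * 10, p)
        assert np.all(ex > 0) and np.all(ex < 1)

    def test_matches_two_layer_oracle(self, rng):
        w1 = rng.normal(size=(2, 4))
        w2 = rng.normal(size=(4, 2))
        sq = rng.normal(size=4)
        got = se_excite(sq, SEParams(w1=w1, w2=w2))
        hidden = np.array([max(0.0, sum(w1[i, j] * sq[j] for j in range(4)))
                           for i in range(2)])
        want = sigmoid(np.array([sum(w2[i, j] * hidden[j] for j in range(2))
                                 for i in range(4)]))
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_shape_mismatch_rejected(self):
        p = SEParams(w1=np.zeros((2, 4)), w2=np.zeros((4, 2)))
        with pytest.raises(ValueError):
            se_excite(np.ones(3), p)
        with pytest.raises(ValueError):
            SEParams(w1=np.zeros((2, 4)), w2=np.zeros((4, 3)))


class TestSeBasicBlock:
    def test_zero_convs_identity_shortcut_passes_input(self, rng):
        block = SEBasicBlock(4, 4, use_se=True, se_reduction=2, rng=rng)
        block.conv1.params["weight"][...] = 0.0
        block.conv2.params["weight"][...] = 0.0
        x = rng.uniform(0.1, 1.0, size=(1, 4, 6, 6))  # non-negative input
        np.testing.assert_allclose(block.forward(x), x, atol=1e-12)

    def test_stride2_stage_transition_shape(self, rng):
        block = SEBasicBlock(4, 8, stride=2, use_se=True, se_reduction=2,
                             rng=rng)
        y = block.forward(rng.normal(size=(2, 4, 16, 16)))
        assert y.shape == (2, 8, 8, 8)

    def test_matches_explicit_composition(self, rng):
        """conv -> bn -> relu -> conv -> bn -> SE-scale -> add -> relu,
        recomputed step by step outside the block."""
        block = SEBasicBlock(2, 2, use_se=True, se_reduction=1, rng=rng)
        x = rng.normal(size=(1, 2, 4, 4))
        y1 = np.maximum(block.bn1.forward(block.conv1.forward(x)), 0.0)
        y2 = block.bn2.forward(block.conv2.forward(y1))
        sq = y2.mean(axis=(2, 3))
        hid = np.maximum(sq @ block.se.params["w1"].T + block.se.params["b1"],
                         0.0)
        ex = sigmoid(hid @ block.se.params["w2"].T + block.se.params["b2"])
        want = np.maximum(y2 * ex[:, :, None, None] + x, 0.0)
        np.testing.assert_allclose(block.forward(x), want, atol=1e-10)

    def test_saturated_se_equals_plain_block(self, rng):
        """Forcing all SE excitations to ~1 reproduces the plain residual
        basic block."""
        se_block = SEBasicBlock(3, 3, use_se=True, se_reduction=1,
                                rng=np.random.default_rng(0))
        plain = SEBasicBlock(3, 3, use_se=False,
                             rng=np.random.default_rng(0))
        for name in ("conv1", "conv2"):
            getattr(plain, name).params["weight"][...] = \
                getattr(se_block, name).params["weight"]
        se_block.se.params["w2"][...] = 0.0
        se_block.se.params["b2"][...] = 60.0  # sigmoid(60) ~ 1
        x = rng.normal(size=(2, 3, 5, 5))
        np.testing.assert_allclose(se_block.forward(x), plain.forward(x),
                                   rtol=1e-10, atol=1e-12)


class TestBuildModel:
    def test_full_model_two_logits_224(self):
        cfg = ModelConfig(backbone_depth=18, stage_channels=(8, 8, 8, 8),
                          input_side=224, seed=0)
        model = AMSNet(cfg)
        logits = model.predict_logits(
            np.random.default_rng(0).uniform(0, 1, (1, 224, 224)))
        assert logits.shape == (1, 2)

    def test_mvggc_off_single_channel_stem(self, tiny_model_config):
        cfg = ModelConfig(**{**tiny_model_config.__dict__,
                             "use_mvggc": False})
        assert AMSNet(cfg).stem.layers[0].in_channels == 1

    def test_all_eight_flag_combinations_build_and_run(self,
                                                       tiny_model_config):
        x = np.random.default_rng(1).uniform(0, 1, (1, 32, 32))
        for mv, ad, se in itertools.product([False, True], repeat=3):
            cfg = ModelConfig(**{**tiny_model_config.__dict__,
                                 "use_mvggc": mv, "use_adcp": ad,
                                 "use_se": se})
            logits = AMSNet(cfg).predict_logits(x)
            assert logits.shape == (1, 2) and np.all(np.isfinite(logits))

    def test_unsupported_depth_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(backbone_depth=50)

    def test_softmax_of_logits_sums_to_one(self, tiny_model_config, rng):
        model = AMSNet(tiny_model_config)
        p = softmax(model.predict_logits(rng.uniform(0, 1, (3, 32, 32))))
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_deterministic(self, tiny_model_config, rng):
        model = AMSNet(tiny_model_config)
        x = rng.uniform(0, 1, (2, 32, 32))
        np.testing.assert_array_equal(model.predict_logits(x),
                                      model.predict_logits(x))


class TestCountParameters:
    def test_head_difference_between_class_counts(self, tiny_model_config):
        cfg2 = tiny_model_config
        cfg1000 = ModelConfig(**{**cfg2.__dict__, "num_classes": 1000})
        c_last = cfg2.stage_channels[-1]
        diff = count_parameters(cfg1000) - count_parameters(cfg2)
        assert diff == (1000 - 2) * c_last + (1000 - 2)

    def test_invariant_to_init_seed(self, tiny_model_config):
        cfg_b = ModelConfig(**{**tiny_model_config.__dict__, "seed": 99})
        assert count_parameters(tiny_model_config) == count_parameters(cfg_b)

    def test_plain_resnet18_trunk_shape_arithmetic(self):
        """Independent shape-product sum for the no-extras baseline."""
        ch = (4, 8, 16, 32)
        cfg = ModelConfig(use_mvggc=False, use_adcp=False, use_se=False,
                          backbone_depth=18, stage_channels=ch, input_side=32)

        def conv(cin, cout, k):
            return cin * cout * k * k

        def bn(c):
            return 2 * c

        expected = conv(1, ch[0], 7) + bn(ch[0])  # stem
        blocks = [(ch[0], ch[0]), (ch[0], ch[0]),
                  (ch[0], ch[1]), (ch[1], ch[1]),
                  (ch[1], ch[2]), (ch[2], ch[2]),
                  (ch[2], ch[3]), (ch[3], ch[3])]
        for cin, cout in blocks:
            expected += conv(cin, cout, 3) + bn(cout) \
                + conv(cout, cout, 3) + bn(cout)
            if cin != cout:  # projection shortcut
                expected += conv(cin, cout, 1) + bn(cout)
        expected += ch[3] * 2 + 2  # head
        assert count_parameters(cfg) == expected


class TestCheckpointIo:
    def test_round_trip_preserves_outputs(self, tmp_path, tiny_model_config,
                                          rng):
        model = AMSNet(tiny_model_config)
        x = rng.uniform(0, 1, (2, 32, 32))
        want = model.predict_logits(x)
        save_checkpoint(model, tmp_path / "ckpt.npz")
        back = load_checkpoint(tmp_path / "ckpt.npz")
        np.testing.assert_array_equal(back.predict_logits(x), want)
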