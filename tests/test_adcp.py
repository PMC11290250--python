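"""Dilated pyramid and channel/spatial attention vs brute-force oracles."""

import numpy as np
import pytest

from amsnet import (
    ADCP,
    AdcpConfig,
    CBAM,
    ChannelAttention,
    SpatialAttention,
    adcp_forward,
    cbam_apply,
    channel_attention,
    dilated_pyramid,
    spatial_attention,
)
from amsnet.nn.layers import Conv2d


def sigmoid(v):
    return 1.0 / (1.0 + np.exp(-v))


def conv2d_oracle(x, w, bias=None, stride=1, pad=0, dil=1):
    """Direct nested-loop 2-D convolution on a (C,H,W) map."""
    c_in, h, wd = x.shape
    c_out, _, k, _ = w.shape
    xp = np.zeros((c_in, h + 2 * pad, wd + 2 * pad))
    xp[:, pad:pad + h, pad:pad + wd] = x
    ho = (h + 2 * pad - dil * (k - 1) - 1) // stride + 1
    wo = (wd + 2 * pad - dil * (k - 1) - 1) // stride + 1
    out = np.zeros((c_out, ho, wo))
    for o in range(c_out):
        for i in range(ho):
            for j in range(wo):
                acc = 0.0
                for c in range(c_in):
                    for a in range(k):
                        for b in range(k):
                            acc += w[o, c, a, b] * \
                                xp[c, i * stride + a * dil,
                                   j * stride + b * dil]
                out[o, i, j] = acc + (bias[o] if bias is not None else 0.0)
    return out


def channel_attention_oracle(x, w0, b0, w1, b1):
    """Scalar evaluation: sigmoid(MLP(avgpool) + MLP(maxpool))."""
    c = x.shape[0]
    avg = np.array([x[k].mean() for k in range(c)])
    mx = np.array([x[k].max() for k in range(c)])

    def mlp(v):
        hidden = np.maximum(w0 @ v + b0, 0.0)
        return w1 @ hidden + b1

    return sigmoid(mlp(avg) + mlp(mx))


def spatial_attention_oracle(x, kernel, bias):
    """Channelwise avg/max maps -> 7x7 conv -> sigmoid, all in loops."""
    avg = x.mean(axis=0)
    mx = x.max(axis=0)
    cat = np.stack([avg, mx])
    k = kernel.shape[-1]
    z = conv2d_oracle(cat, kernel, bias=np.array([bias]), pad=k // 2)
    return sigmoid(z[0])


class TestDilatedPyramid:
    def test_default_has_four_branches(self, rng):
        cfg = AdcpConfig(branch_channels=3)
        x = rng.normal(size=(2, 40, 40))
        out = dilated_pyramid(x, cfg, rng=rng)
        assert out.shape == (4 * 3, 40, 40)
        assert cfg.dilation_rates == (6, 12, 18)

    @pytest.mark.parametrize("h,w", [(40, 40), (37, 41)])
    def test_spatial_size_preserved(self, rng, h, w):
        cfg = AdcpConfig(dilation_rates=(2, 4), branch_channels=2)
        x = rng.normal(size=(1, h, w))
        assert dilated_pyramid(x, cfg, rng=rng).shape[1:] == (h, w)

    @pytest.mark.parametrize("rate", [6, 12, 18])
    def test_impulse_support_radius_is_rate(self, rate):
        """A 3x3 dilated kernel responds only at offsets {-r, 0, +r}."""
        side = 2 * rate + 5
        x = np.zeros((1, 1, side, side))
        mid = side // 2
        x[0, 0, mid, mid] = 1.0
        conv = Conv2d(1, 1, 3, padding=rate, dilation=rate, bias=False)
        conv.params["weight"][...] = 1.0
        y = conv.forward(x)[0, 0]
        nz_r, nz_c = np.nonzero(y)
        offsets = {(r - mid, c - mid) for r, c in zip(nz_r, nz_c)}
        assert offsets == {(dr, dc) for dr in (-rate, 0, rate)
                           for dc in (-rate, 0, rate)}

    def test_dilated_conv_matches_loop_oracle(self, rng):
        x = rng.normal(size=(2, 15, 15))
        conv = Conv2d(2, 3, 3, padding=6, dilation=6, rng=rng)
        got = conv.forward(x[None])[0]
        want = conv2d_oracle(x, conv.params["weight"], conv.params["bias"],
                             pad=6, dil=6)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            AdcpConfig(kernel_size=4)
        with pytest.raises(ValueError):
            AdcpConfig(dilation_rates=(6, 6, 12))


class TestChannelAttention:
    def test_zero_weights_give_half(self, rng):
        x = rng.normal(size=(3, 4, 4))
        w0 = np.zeros((1, 3))
        w1 = np.zeros((3, 1))
        np.testing.assert_allclose(channel_attention(x, w0, w1), 0.5)

    def test_constant_input_symmetry(self, rng):
        """Spatially constant input: avg and max descriptors coincide, so
        the gate equals sigmoid(2 * MLP(v))."""
        v = np.array([0.3, -0.2, 0.8])
        x = np.broadcast_to(v[:, None, None], (3, 5, 5)).copy()
        w0 = rng.normal(size=(2, 3)) * 0.5
        w1 = rng.normal(size=(3, 2)) * 0.5
        got = channel_attention(x, w0, w1)
        mlp = w1 @ np.maximum(w0 @ v, 0.0)
        np.testing.assert_allclose(got, sigmoid(2 * mlp), rtol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        x = rng.normal(size=(3, 4, 4))
        w0 = rng.normal(size=(2, 3)) * 0.3
        b0 = rng.normal(size=2) * 0.1
        w1 = rng.normal(size=(3, 2)) * 0.3
        b1 = rng.normal(size=3) * 0.1
        got = channel_attention(x, w0, w1, b0, b1)
        want = channel_attention_oracle(x, w0, b0, w1, b1)
        np.testing.assert_allclose(got, want, atol=1e-6)
        assert np.all(got > 0) and np.all(got < 1)

    def test_shape_mismatch_rejected(self, rng):
        x = rng.normal(size=(3, 4, 4))
        with pytest.raises(ValueError):
            channel_attention(x, np.zeros((2, 4)), np.zeros((3, 2)))


class TestSpatialAttention:
    def test_zero_kernel_gives_half(self, rng):
        x = rng.normal(size=(3, 6, 6))
        out = spatial_attention(x, np.zeros((1, 2, 7, 7)))
        np.testing.assert_allclose(out, 0.5)

    def test_constant_input_constant_map(self, rng):
        x = np.broadcast_to(np.array([0.4, -1.0])[:, None, None],
                            (2, 9, 9)).copy()
        kern = rng.normal(size=(1, 2, 3, 3))
        out = spatial_attention(x, kern)
        interior = out[1:-1, 1:-1]  # away from padding effects
        np.testing.assert_allclose(interior, interior[0, 0], rtol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        x = rng.normal(size=(3, 8, 8))
        kern = rng.normal(size=(1, 2, 7, 7)) * 0.2
        got = spatial_attention(x, kern, bias=0.1)
        want = spatial_attention_oracle(x, kern, 0.1)
        np.testing.assert_allclose(got, want, atol=1e-6)
        assert np.all(got > 0) and np.all(got < 1)

    def test_wrong_kernel_channels_rejected(self, rng):
        with pytest.raises(ValueError):
            spatial_attention(rng.normal(size=(3, 8, 8)),
                              np.zeros((1, 3, 7, 7)))


class TestCbam:
    def _saturate(self, cbam):
        for key in ("w0", "b0", "w1"):
            cbam.channel_att.params[key][...] = 0.0
        cbam.channel_att.params["b1"][...] = 50.0
        cbam.spatial_att.conv.params["weight"][...] = 0.0
        cbam.spatial_att.conv.params["bias"][...] = 50.0

    def test_saturated_attention_is_identity(self, rng):
        x = rng.normal(size=(4, 6, 6))
        cbam = CBAM(4, reduction=2)
        self._saturate(cbam)
        np.testing.assert_allclose(cbam_apply(x, cbam), x, atol=1e-6)

    def test_shape_preserved(self, rng):
        for shape in [(2, 5, 7), (8, 3, 3)]:
            x = rng.normal(size=shape)
            out = cbam_apply(x, CBAM(shape[0], reduction=2, rng=rng))
            assert out.shape == shape

    def test_attention_only_attenuates(self, rng):
        x = rng.normal(size=(4, 6, 6))
        out = cbam_apply(x, CBAM(4, reduction=2, rng=rng))
        assert np.all(np.abs(out) <= np.abs(x) + 1e-12)

    def test_composition_matches_scalar_oracle(self, rng):
        x = rng.normal(size=(3, 5, 5))
        cbam = CBAM(3, reduction=1, spatial_kernel=3, rng=rng)
        ca = cbam.channel_att.params
        att_c = channel_attention_oracle(x, ca["w0"], ca["b0"],
                                         ca["w1"], ca["b1"])
        y1 = np.empty_like(x)
        for k in range(3):
            y1[k] = att_c[k] * x[k]
        att_s = spatial_attention_oracle(
            y1, cbam.spatial_att.conv.params["weight"],
            cbam.spatial_att.conv.params["bias"][0])
        want = y1 * att_s[None]
        np.testing.assert_allclose(cbam_apply(x, cbam), want, atol=1e-6)


class TestAdcpForward:
    def test_shape_contract_stride2(self, rng):
        cfg = AdcpConfig(dilation_rates=(2, 3), branch_channels=4,
                         reduction_ratio=2, fusion_out_channels=8,
                         downsample_stride=2)
        x = rng.normal(size=(4, 32, 32))
        out = adcp_forward(x, cfg, rng=rng)
        assert out.shape == (8, 16, 16)

    def test_stride1_preserves_size(self, rng):
        cfg = AdcpConfig(dilation_rates=(2,), branch_channels=2,
                         reduction_ratio=1, fusion_out_channels=2,
                         downsample_stride=1)
        x = rng.normal(size=(2, 11, 11))
        assert adcp_forward(x, cfg, rng=rng).shape == (2, 11, 11)

    def test_odd_input_ceil_division(self, rng):
        cfg = AdcpConfig(dilation_rates=(2,), branch_channels=2,
                         reduction_ratio=1, fusion_out_channels=3,
                         downsample_stride=2)
        x = rng.normal(size=(2, 15, 15))
        assert adcp_forward(x, cfg, rng=rng).shape == (3, 8, 8)

    def test_saturated_cbam_mean_fusion_equals_branch_mean(self, rng):
        """With attention saturated to 1, BN bypassed, and the 1x1 fusion
        kernel set to averaging, the output is the branch mean, downsampled."""
        cfg = AdcpConfig(dilation_rates=(2, 3), branch_channels=3,
                         reduction_ratio=1, fusion_out_channels=1,
                         downsample_stride=2)
        module = ADCP(3, cfg, rng=rng)
        # saturate CBAM gates
        for key in ("w0", "b0", "w1"):
            module.cbam.channel_att.params[key][...] = 0.0
        module.cbam.channel_att.params["b1"][...] = 50.0
        module.cbam.spatial_att.conv.params["weight"][...] = 0.0
        module.cbam.spatial_att.conv.params["bias"][...] = 50.0
        # averaging fusion, identity-like BN
        nc = cfg.concat_channels
        module.fusion.layers[0].params["weight"][...] = 1.0 / nc
        bn = module.fusion.layers[1]
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 1.0 - bn.eps
        x = rng.uniform(0.5, 1.5, size=(3, 12, 12))
        pyramid_out = module.pyramid.forward(x[None])[0]
        want = np.maximum(pyramid_out.mean(axis=0), 0.0)[::2, ::2]
        got = module.forward(x[None])[0]
        np.testing.assert_allclose(got[0], want, atol=1e-6)
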