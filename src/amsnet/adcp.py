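"""Attentional dilated convolutional pyramid (ADCP).

Multi-scale feature extraction in the ASPP style — parallel 3x3 dilated
convolutions at rates 6/12/18 plus a global-pooling branch, concatenated —
followed by CBAM-style channel and spatial attention over the concatenated
map, then a 1x1 fusion convolution that reduces channels and (with stride 2)
takes over the stem's downsampling role.

Channel attention pools the map spatially (average and max), pushes both
descriptors through one shared bottleneck MLP and sigmoids their sum.
Spatial attention pools across channels (average and max), convolves the
2-channel stack with a 7x7 kernel and sigmoids the result.  Both gates lie
strictly in (0,1) and are applied multiplicatively, so attention can only
attenuate activations, never amplify them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn.layers import (
    BatchNorm2d,
    Conv2d,
    Module,
    ReLU,
    Sequential,
    sigmoid,
)

__all__ = [
    "AdcpConfig",
    "ChannelAttention",
    "SpatialAttention",
    "CBAM",
    "DilatedPyramid",
    "ADCP",
    "dilated_pyramid",
    "channel_attention",
    "spatial_attention",
    "cbam_apply",
    "adcp_forward",
]


@dataclass
class AdcpConfig:
    dilation_rates: tuple[int, ...] = (6, 12, 18)
    branch_channels: int = 64
    kernel_size: int = 3
    reduction_ratio: int = 16
    spatial_kernel: int = 7
    fusion_out_channels: int = 64
    downsample_stride: int = 2

    def __post_init__(self):
        self.dilation_rates = tuple(int(r) for r in self.dilation_rates)
        if len(set(self.dilation_rates)) != len(self.dilation_rates):
            raise ValueError("dilation rates must be distinct")
        if any(r < 1 for r in self.dilation_rates):
            raise ValueError("dilation rates must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")

    @property
    def n_branches(self) -> int:
        return len(self.dilation_rates) + 1  # + pooling branch

    @property
    def concat_channels(self) -> int:
        return self.n_branches * self.branch_channels


class ChannelAttention(Module):
    """Shared-MLP channel gate: sigmoid(MLP(avgpool) + MLP(maxpool))."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        hidden = max(1, channels // reduction)
        self.hidden = hidden
        rng = rng or np.random.default_rng(0)
        self.add_param("w0", rng.normal(0, np.sqrt(2.0 / channels),
                                        size=(hidden, channels)))
        self.add_param("b0", np.zeros(hidden))
        self.add_param("w1", rng.normal(0, np.sqrt(2.0 / hidden),
                                        size=(channels, hidden)))
        self.add_param("b1", np.zeros(channels))
        self._cache = None

    def _mlp(self, v):
        z = v @ self.params["w0"].T + self.params["b0"]
        h = np.maximum(z, 0.0)
        return h @ self.params["w1"].T + self.params["b1"], z, h

    def forward(self, x, training=False):
        if x.ndim != 4 or x.shape[1] != self.channels:
            raise ValueError(f"expected (N,{self.channels},H,W), got {x.shape}")
        n, c, h, w = x.shape
        avg = x.mean(axis=(2, 3))
        flat = x.reshape(n, c, h * w)
        mx_idx = flat.argmax(axis=2)
        mx = np.take_along_axis(flat, mx_idx[:, :, None], axis=2)[:, :, 0]
        out_a, z_a, h_a = self._mlp(avg)
        out_m, z_m, h_m = self._mlp(mx)
        att = sigmoid(out_a + out_m)
        if training:
            self._cache = (x.shape, avg, mx, mx_idx, z_a, h_a, z_m, h_m, att)
        return att

    def backward(self, d_att):
        x_shape, avg, mx, mx_idx, z_a, h_a, z_m, h_m, att = self._cache
        n, c, h, w = x_shape
        ds = d_att * att * (1.0 - att)

        def mlp_back(ds, z, hid, v):
            self.grads["w1"] += ds.T @ hid
            self.grads["b1"] += ds.sum(axis=0)
            dh = ds @ self.params["w1"]
            dz = dh * (z > 0)
            self.grads["w0"] += dz.T @ v
            self.grads["b0"] += dz.sum(axis=0)
            return dz @ self.params["w0"]

        d_avg = mlp_back(ds, z_a, h_a, avg)
        d_mx = mlp_back(ds, z_m, h_m, mx)
        dx = np.broadcast_to(d_avg[:, :, None, None] / (h * w),
                             x_shape).copy()
        dflat = np.zeros((n, c, h * w))
        np.put_along_axis(dflat, mx_idx[:, :, None], d_mx[:, :, None], axis=2)
        dx += dflat.reshape(x_shape)
        return dx


class SpatialAttention(Module):
    """7x7-conv spatial gate over channelwise avg/max pooled maps."""

    def __init__(self, kernel_size: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("spatial kernel must be odd")
        self.conv = Conv2d(2, 1, kernel_size, padding=kernel_size // 2,
                           rng=rng or np.random.default_rng(0))
        self._cache = None

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        avg_map = x.mean(axis=1, keepdims=True)
        mx_idx = x.argmax(axis=1)
        mx_map = np.take_along_axis(x, mx_idx[:, None], axis=1)
        cat = np.concatenate([avg_map, mx_map], axis=1)
        z = self.conv.forward(cat, training=training)
        att = sigmoid(z)
        if training:
            self._cache = (x.shape, mx_idx, att)
        return att[:, 0]

    def backward(self, d_att):
        x_shape, mx_idx, att = self._cache
        n, c, h, w = x_shape
        ds = (d_att[:, None] * att * (1.0 - att))
        dcat = self.conv.backward(ds)
        dx = np.broadcast_to(dcat[:, 0:1] / c, x_shape).copy()
        d_mx = dcat[:, 1]
        scatter = np.zeros(x_shape)
        np.put_along_axis(scatter, mx_idx[:, None], d_mx[:, None], axis=1)
        return dx + scatter


class CBAM(Module):
    """Sequential channel-then-spatial attention, applied multiplicatively."""

    def __init__(self, channels: int, reduction: int = 16,
                 spatial_kernel: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channel_att = ChannelAttention(channels, reduction, rng=rng)
        self.spatial_att = SpatialAttention(spatial_kernel, rng=rng)
        self._cache = None

    def forward(self, x, training=False):
        ac = self.channel_att.forward(x, training=training)
        y1 = x * ac[:, :, None, None]
        asp = self.spatial_att.forward(y1, training=training)
        y2 = y1 * asp[:, None]
        if training:
            self._cache = (x, ac, y1, asp)
        return y2

    def backward(self, grad):
        x, ac, y1, asp = self._cache
        d_asp = (grad * y1).sum(axis=1)
        d_y1 = grad * asp[:, None]
        d_y1 += self.spatial_att.backward(d_asp)
        d_ac = (d_y1 * x).sum(axis=(2, 3))
        dx = d_y1 * ac[:, :, None, None]
        dx += self.channel_att.backward(d_ac)
        return dx


class _PoolBranch(Module):
    """ASPP image-level branch: GAP -> 1x1 conv -> BN -> ReLU -> broadcast."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, 1, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_channels)
        self.relu = ReLU()
        self._cache = None

    def forward(self, x, training=False):
        n, c, h, w = x.shape
        g = x.mean(axis=(2, 3))[:, :, None, None]
        y = self.relu.forward(
            self.bn.forward(self.conv.forward(g, training=training),
                            training=training), training=training)
        if training:
            self._cache = (x.shape,)
        return np.broadcast_to(y, (n, y.shape[1], h, w)).copy()

    def backward(self, grad):
        (x_shape,) = self._cache
        n, c, h, w = x_shape
        dg = grad.sum(axis=(2, 3), keepdims=True)
        dg = self.conv.backward(self.bn.backward(self.relu.backward(dg)))
        return np.broadcast_to(dg / (h * w), x_shape).copy()


class DilatedPyramid(Module):
    """Parallel dilated branches plus pooling branch, concatenated."""

    def __init__(self, in_channels: int, cfg: AdcpConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.branches = []
        for i, rate in enumerate(cfg.dilation_rates):
            pad = rate * (cfg.kernel_size - 1) // 2
            branch = Sequential(
                Conv2d(in_channels, cfg.branch_channels, cfg.kernel_size,
                       padding=pad, dilation=rate, bias=False, rng=rng),
                BatchNorm2d(cfg.branch_channels),
                ReLU(),
            )
            self.branches.append(branch)
            self._children[f"branch{i}"] = branch
        self.pool_branch = _PoolBranch(in_channels, cfg.branch_channels,
                                       rng=rng)

    def forward(self, x, training=False):
        outs = [b.forward(x, training=training) for b in self.branches]
        outs.append(self.pool_branch.forward(x, training=training))
        return np.concatenate(outs, axis=1)

    def backward(self, grad):
        bc = self.cfg.branch_channels
        parts = [grad[:, i * bc:(i + 1) * bc]
                 for i in range(self.cfg.n_branches)]
        dx = self.pool_branch.backward(parts[-1])
        for b, g in zip(self.branches, parts[:-1]):
            dx = dx + b.backward(g)
        return dx


class ADCP(Module):
    """pyramid -> CBAM -> strided 1x1 fusion conv -> BN -> ReLU."""

    def __init__(self, in_channels: int, cfg: AdcpConfig | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        cfg = cfg or AdcpConfig()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.pyramid = DilatedPyramid(in_channels, cfg, rng=rng)
        self.cbam = CBAM(cfg.concat_channels, cfg.reduction_ratio,
                         cfg.spatial_kernel, rng=rng)
        self.fusion = Sequential(
            Conv2d(cfg.concat_channels, cfg.fusion_out_channels, 1,
                   stride=cfg.downsample_stride, bias=False, rng=rng),
            BatchNorm2d(cfg.fusion_out_channels),
            ReLU(),
        )

    def forward(self, x, training=False):
        msf = self.pyramid.forward(x, training=training)
        msf2 = self.cbam.forward(msf, training=training)
        return self.fusion.forward(msf2, training=training)

    def backward(self, grad):
        return self.pyramid.backward(
            self.cbam.backward(self.fusion.backward(grad)))


# ---------------------------------------------------------------------------
# Thin functional wrappers over single (C, H, W) feature maps.

def _as_batch(x):
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError("feature map must be (C, H, W)")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map must be finite")
    return x[None]


def dilated_pyramid(x: np.ndarray, cfg: AdcpConfig | None = None,
                    module: DilatedPyramid | None = None,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    xb = _as_batch(x)
    cfg = cfg or AdcpConfig()
    module = module or DilatedPyramid(xb.shape[1], cfg, rng=rng)
    return module.forward(xb)[0]


def channel_attention(i: np.ndarray, w0: np.ndarray, w1: np.ndarray,
                      b0: np.ndarray | None = None,
                      b1: np.ndarray | None = None) -> np.ndarray:
    """Evaluate the channel gate with explicit MLP weights; returns (C,)."""
    xb = _as_batch(i)
    c = xb.shape[1]
    w0 = np.asarray(w0, dtype=np.float64)
    w1 = np.asarray(w1, dtype=np.float64)
    if w0.shape[1] != c or w1.shape[0] != c or w0.shape[0] != w1.shape[1]:
        raise ValueError("MLP weight shapes inconsistent with channel count")
    mod = ChannelAttention(c, reduction=max(1, c // w0.shape[0]))
    mod.params["w0"] = w0
    mod.params["w1"] = w1
    mod.params["b0"] = np.zeros(w0.shape[0]) if b0 is None else np.asarray(b0, dtype=np.float64)
    mod.params["b1"] = np.zeros(c) if b1 is None else np.asarray(b1, dtype=np.float64)
    return mod.forward(xb)[0]


def spatial_attention(i: np.ndarray, conv7: np.ndarray,
                      bias: float = 0.0) -> np.ndarray:
    """Evaluate the spatial gate with an explicit (1,2,k,k) kernel."""
    xb = _as_batch(i)
    conv7 = np.asarray(conv7, dtype=np.float64)
    if conv7.ndim != 4 or conv7.shape[:2] != (1, 2):
        raise ValueError("kernel must be shaped (1, 2, k, k)")
    mod = SpatialAttention(conv7.shape[-1])
    mod.conv.params["weight"] = conv7
    mod.conv.params["bias"] = np.asarray([bias], dtype=np.float64)
    return mod.forward(xb)[0]


def cbam_apply(msf: np.ndarray, module: CBAM) -> np.ndarray:
    return module.forward(_as_batch(msf))[0]


def adcp_forward(x: np.ndarray, cfg: AdcpConfig | None = None,
                 module: ADCP | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    xb = _as_batch(x)
    module = module or ADCP(xb.shape[1], cfg, rng=rng)
    return module.forward(xb)[0]
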