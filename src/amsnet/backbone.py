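"""SE-augmented residual backbone and full network assembly.

The classifier is a shallow residual trunk (basic blocks, depth 18 or 34)
whose blocks are recalibrated by squeeze-and-excitation (SE) gates:

    SQ_k = mean over (i,j) of F_k(i,j)            (squeeze)
    EX   = sigmoid(W2 . ReLU(W1 . SQ))            (excite)
    out  = EX * F~ + shortcut                     (recalibrated residual)

The full model is MVGGC input stack -> 7x7/2 stem -> ADCP (or 3x3/2
max-pool) -> four residual stages -> global average pool -> linear head.
Each of the three additions (multi-view input, ADCP, SE) has an on/off flag
so every ablation variant is constructible from the same config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .adcp import ADCP, AdcpConfig
from .mvggc import GammaSpec, build_multiview
from .nn.layers import (
    BatchNorm2d,
    Conv2d,
    GlobalAvgPool2d,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    sigmoid,
)

__all__ = [
    "SEParams",
    "ModelConfig",
    "SEBlock",
    "SEBasicBlock",
    "AMSNet",
    "se_squeeze",
    "se_excite",
    "se_basic_block",
    "build_model",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

_STAGE_BLOCKS = {18: (2, 2, 2, 2), 34: (3, 4, 6, 3)}


@dataclass
class SEParams:
    """Explicit SE excitation weights (functional interface)."""

    w1: np.ndarray  # (C/r, C) reducing layer
    w2: np.ndarray  # (C, C/r) restoring layer
    reduction: int = 16

    def __post_init__(self):
        self.w1 = np.asarray(self.w1, dtype=np.float64)
        self.w2 = np.asarray(self.w2, dtype=np.float64)
        if self.w1.ndim != 2 or self.w2.ndim != 2 \
                or self.w1.shape[0] != self.w2.shape[1] \
                or self.w1.shape[1] != self.w2.shape[0]:
            raise ValueError("w1 (C/r,C) and w2 (C,C/r) shapes inconsistent")


@dataclass
class ModelConfig:
    """Architecture hyperparameters, including the three ablation flags."""

    use_mvggc: bool = True
    use_adcp: bool = True
    use_se: bool = True
    backbone_depth: int = 34
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    num_classes: int = 2
    se_reduction: int = 16
    adcp: AdcpConfig | None = None
    gamma: GammaSpec = field(default_factory=GammaSpec)
    input_side: int = 224
    seed: int = 0

    def __post_init__(self):
        if self.backbone_depth not in _STAGE_BLOCKS:
            raise ValueError(
                f"backbone_depth must be one of {sorted(_STAGE_BLOCKS)}")
        self.stage_channels = tuple(int(c) for c in self.stage_channels)
        if len(self.stage_channels) != 4:
            raise ValueError("stage_channels must list 4 stages")
        if self.adcp is None:
            self.adcp = AdcpConfig(
                branch_channels=self.stage_channels[0],
                fusion_out_channels=self.stage_channels[0])

    @property
    def in_channels(self) -> int:
        return self.gamma.n_views if self.use_mvggc else 1

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stage_channels"] = list(self.stage_channels)
        d["adcp"]["dilation_rates"] = list(self.adcp.dilation_rates)
        d["gamma"]["gammas"] = list(self.gamma.gammas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if isinstance(d.get("adcp"), dict):
            d["adcp"] = AdcpConfig(**d["adcp"])
        if isinstance(d.get("gamma"), dict):
            d["gamma"] = GammaSpec(**d["gamma"])
        return cls(**d)


class SEBlock(Module):
    """Squeeze-and-excitation channel gate."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.channels = channels
        self.add_param("w1", rng.normal(0, np.sqrt(2.0 / channels),
                                        size=(hidden, channels)))
        self.add_param("b1", np.zeros(hidden))
        self.add_param("w2", rng.normal(0, np.sqrt(2.0 / hidden),
                                        size=(channels, hidden)))
        self.add_param("b2", np.zeros(channels))
        self._cache = None

    def forward(self, x, training=False):
        sq = x.mean(axis=(2, 3))
        z = sq @ self.params["w1"].T + self.params["b1"]
        h = np.maximum(z, 0.0)
        ex = sigmoid(h @ self.params["w2"].T + self.params["b2"])
        y = x * ex[:, :, None, None]
        if training:
            self._cache = (x, sq, z, h, ex)
        return y

    def backward(self, grad):
        x, sq, z, h, ex = self._cache
        _, _, hh, ww = x.shape
        d_ex = (grad * x).sum(axis=(2, 3))
        dx = grad * ex[:, :, None, None]
        ds = d_ex * ex * (1.0 - ex)
        self.grads["w2"] += ds.T @ h
        self.grads["b2"] += ds.sum(axis=0)
        dh = ds @ self.params["w2"]
        dz = dh * (z > 0)
        self.grads["w1"] += dz.T @ sq
        self.grads["b1"] += dz.sum(axis=0)
        d_sq = dz @ self.params["w1"]
        dx += np.broadcast_to(d_sq[:, :, None, None] / (hh * ww), x.shape)
        return dx


class SEBasicBlock(Module):
    """Two-3x3-conv residual basic block with optional SE recalibration.

    The SE gate acts on the second convolution's normalized output, before
    the shortcut addition.  A strided 1x1 projection shortcut is inserted
    whenever stride or channel count changes.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 use_se: bool = True, se_reduction: int = 16,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride=stride,
                            padding=1, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(out_channels, out_channels, 3, padding=1,
                            bias=False, rng=rng)
        self.bn2 = BatchNorm2d(out_channels)
        self.use_se = use_se
        if use_se:
            self.se = SEBlock(out_channels, se_reduction, rng=rng)
        self.has_projection = stride != 1 or in_channels != out_channels
        if self.has_projection:
            self.proj = Sequential(
                Conv2d(in_channels, out_channels, 1, stride=stride,
                       bias=False, rng=rng),
                BatchNorm2d(out_channels),
            )
        self.relu_out = ReLU()

    def forward(self, x, training=False):
        y = self.relu1.forward(
            self.bn1.forward(self.conv1.forward(x, training), training),
            training)
        y = self.bn2.forward(self.conv2.forward(y, training), training)
        if self.use_se:
            y = self.se.forward(y, training=training)
        shortcut = self.proj.forward(x, training) if self.has_projection else x
        return self.relu_out.forward(y + shortcut, training=training)

    def backward(self, grad):
        grad = self.relu_out.backward(grad)
        d_short = grad
        d_main = grad
        if self.use_se:
            d_main = self.se.backward(d_main)
        d_main = self.conv2.backward(self.bn2.backward(d_main))
        d_main = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(d_main)))
        if self.has_projection:
            d_short = self.proj.backward(d_short)
        return d_main + d_short


class AMSNet(Module):
    """Full classifier; see module docstring for the layer plan."""

    def __init__(self, cfg: ModelConfig | None = None):
        super().__init__()
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        c0 = cfg.stage_channels[0]
        self.stem = Sequential(
            Conv2d(cfg.in_channels, c0, 7, stride=2, padding=3, bias=False,
                   rng=rng),
            BatchNorm2d(c0),
            ReLU(),
        )
        if cfg.use_adcp:
            self.reduce = ADCP(c0, cfg.adcp, rng=rng)
        else:
            self.reduce = MaxPool2d(3, 2, 1)
        blocks_per_stage = _STAGE_BLOCKS[cfg.backbone_depth]
        stages = []
        in_ch = cfg.adcp.fusion_out_channels if cfg.use_adcp else c0
        for s, (n_blocks, out_ch) in enumerate(
                zip(blocks_per_stage, cfg.stage_channels)):
            for b in range(n_blocks):
                stride = 2 if (s > 0 and b == 0) else 1
                stages.append(SEBasicBlock(
                    in_ch, out_ch, stride=stride, use_se=cfg.use_se,
                    se_reduction=cfg.se_reduction, rng=rng))
                in_ch = out_ch
        self.stages = Sequential(*stages)
        self.gap = GlobalAvgPool2d()
        self.head = Linear(cfg.stage_channels[-1], cfg.num_classes, rng=rng)

    def prepare_input(self, images: np.ndarray) -> np.ndarray:
        """(N,H,W) grayscale batch -> (N,C,H,W) network input."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == 2:
            images = images[None]
        if images.ndim != 3:
            raise ValueError("expected (N, H, W) grayscale batch")
        if self.cfg.use_mvggc:
            return np.stack([build_multiview(im, self.cfg.gamma).views
                             for im in images])
        return images[:, None]

    def forward(self, x, training=False):
        x = self.stem.forward(x, training=training)
        x = self.reduce.forward(x, training=training)
        x = self.stages.forward(x, training=training)
        x = self.gap.forward(x, training=training)
        return self.head.forward(x, training=training)

    def backward(self, grad):
        grad = self.head.backward(grad)
        grad = self.gap.backward(grad)
        grad = self.stages.backward(grad)
        grad = self.reduce.backward(grad)
        return self.stem.backward(grad)

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        return self.forward(self.prepare_input(images), training=False)


# ---------------------------------------------------------------------------
# Functional forms


def se_squeeze(f: np.ndarray) -> np.ndarray:
    """Global average pool a (C,H,W) map to a (C,) descriptor."""
    f = np.asarray(f, dtype=np.float64)
    if f.ndim != 3:
        raise ValueError("feature map must be (C, H, W)")
    if f.shape[1] == 0 or f.shape[2] == 0:
        raise ValueError("empty spatial extent")
    return f.mean(axis=(1, 2))


def se_excite(sq: np.ndarray, params: SEParams) -> np.ndarray:
    """sigmoid(W2 . ReLU(W1 . sq)); all entries strictly in (0,1)."""
    sq = np.asarray(sq, dtype=np.float64)
    if sq.shape[0] != params.w1.shape[1]:
        raise ValueError("descriptor length does not match W1")
    return sigmoid(params.w2 @ np.maximum(params.w1 @ sq, 0.0))


def se_basic_block(x: np.ndarray, block: SEBasicBlock) -> np.ndarray:
    """Run a single block on one (C,H,W) map in inference mode."""
    x = np.asarray(x, dtype=np.float64)
    return block.forward(x[None])[0]


def build_model(cfg: ModelConfig | None = None) -> AMSNet:
    return AMSNet(cfg)


def count_parameters(cfg_or_model) -> int:
    model = cfg_or_model if isinstance(cfg_or_model, AMSNet) \
        else AMSNet(cfg_or_model)
    return model.n_parameters()


def save_checkpoint(model: AMSNet, path: str | Path) -> None:
    """Weights as .npz with the config as a JSON side-car."""
    path = Path(path)
    state = model.state_dict()
    state.update(model.buffers_dict())
    np.savez(path, **state)
    side = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" \
        else path.with_suffix(".json")
    side.write_text(json.dumps(model.cfg.to_dict(), indent=2))


def load_checkpoint(path: str | Path) -> AMSNet:
    path = Path(path)
    side = path.with_suffix(".json")
    cfg = ModelConfig.from_dict(json.loads(side.read_text()))
    model = AMSNet(cfg)
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    buffers = {k: state.pop(k) for k in list(state) if ".running_" in k}
    model.load_state_dict(state)
    model.load_buffers_dict(buffers)
    return model
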