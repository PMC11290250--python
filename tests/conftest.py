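import numpy as np
import pytest

from amsnet import (
    AdcpConfig,
    ModelConfig,
    PhantomParams,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_phantom_params():
    """Full-geometry phantom at the minimum legal resolution (fast)."""
    return PhantomParams(image_size=224, midbrain_axes=(55.0, 30.0),
                         lesion_radius_range=(6.0, 16.0))


@pytest.fixture
def tiny_model_config():
    """Miniature full network: every module present, shapes minimal."""
    return ModelConfig(
        backbone_depth=18, stage_channels=(4, 4, 8, 8),
        adcp=AdcpConfig(dilation_rates=(2, 3), branch_channels=4,
                        reduction_ratio=2, fusion_out_channels=4),
        se_reduction=2, input_side=32, seed=0)
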