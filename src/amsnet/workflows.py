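"""High-level experiment workflows shared by the test suite, the CLI and
the reproduction script."""

from __future__ import annotations

from dataclasses import dataclass

from .adcp import AdcpConfig
from .backbone import AMSNet, ModelConfig
from .evaluation import evaluate
from .pipeline import SplitSpec, resize_samples, stratified_split
from .synthetic import PhantomParams, generate_dataset
from .training import TrainConfig, TrainHistory, train

__all__ = ["ScaledStudy", "run_scaled_study"]


@dataclass
class ScaledStudy:
    """Result bundle of the scaled-down phantom study."""

    model: AMSNet
    history: TrainHistory
    best_val_accuracy: float
    test_accuracy: float


def run_scaled_study(n_per_class: int = 100, side: int = 64,
                     max_epochs: int = 50, seed: int = 0) -> ScaledStudy:
    """Train the depth-18 scaled-down network on synthetic phantoms.

    Phantoms are generated at 448x448, downsampled with anti-aliasing to
    ``side``, split 6:2:2, and the network is trained with the reference
    optimizer settings (AdamW, lr 1e-4, batch 4) for ``max_epochs`` epochs,
    keeping the best-on-validation checkpoint.
    """
    params = PhantomParams()
    samples = generate_dataset(n_per_class, n_per_class, params, seed=seed)
    samples = resize_samples(samples, side, antialias=True)
    split = stratified_split(samples, SplitSpec(seed=seed))
    model_cfg = ModelConfig(
        backbone_depth=18, stage_channels=(8, 16, 32, 64),
        adcp=AdcpConfig(branch_channels=8, fusion_out_channels=8),
        input_side=side, seed=seed)
    train_cfg = TrainConfig(min_epochs=max_epochs, max_epochs=max_epochs,
                            seed=seed)
    model, history = train(model_cfg, train_cfg, split)
    reports, _ = evaluate(model, split.test)
    return ScaledStudy(model=model, history=history,
                       best_val_accuracy=max(history.val_accuracy),
                       test_accuracy=reports["abnormal"].accuracy)
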