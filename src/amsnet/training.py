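"""Training protocol.

Class-weighted cross-entropy, AdamW (lr 1e-4, batch 4), a train-loss-driven
learning-rate schedule (halve the rate after a patience window without
relative improvement), a minimum epoch count before early stopping, and
best-on-validation checkpointing: the weights that are kept are those of
the epoch with the highest validation accuracy, not the last epoch.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .backbone import AMSNet, ModelConfig
from .nn.losses import weighted_cross_entropy, softmax
from .nn.optim import AdamW
from .pipeline import DatasetSplit
from .synthetic import LABELS, LabeledSample

__all__ = [
    "weighted_cross_entropy",
    "TrainConfig",
    "TrainHistory",
    "auto_class_weights",
    "adapt_lr",
    "train",
    "fit_arrays",
    "samples_to_arrays",
]

REL_IMPROVEMENT = 1e-4  # relative train-loss improvement that resets patience


@dataclass
class TrainConfig:
    batch_size: int = 4
    initial_lr: float = 1e-4
    min_epochs: int = 50
    max_epochs: int = 200
    plateau_patience: int = 5
    lr_decay_factor: float = 0.5
    stop_patience: int = 10
    class_weights: str | tuple[float, ...] = "auto"
    weight_decay: float = 0.01
    betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0.0 < self.lr_decay_factor < 1.0:
            raise ValueError("lr_decay_factor must lie in (0, 1)")
        if self.max_epochs < self.min_epochs:
            raise ValueError("max_epochs must be >= min_epochs")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        """1-based epoch index with the highest validation accuracy
        (ties broken toward the earlier epoch)."""
        if not self.val_accuracy:
            raise ValueError("no epochs recorded")
        return int(np.argmax(self.val_accuracy)) + 1


def auto_class_weights(labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """Inverse-frequency weights: N_total / (K * N_class)."""
    counts = np.bincount(labels, minlength=n_classes).astype(np.float64)
    if np.any(counts == 0):
        raise ValueError("every class must appear in the training set")
    return labels.size / (n_classes * counts)


def _plateau_replay(losses: list[float], cfg: TrainConfig):
    """Replay the plateau rule over a loss trace.

    Returns (lr, epochs_since_improvement).  The rate is halved every time
    ``plateau_patience`` consecutive epochs pass without a relative
    improvement of the running-best train loss; it never increases.
    """
    lr = cfg.initial_lr
    best = np.inf
    since = 0
    for loss in losses:
        if loss < best * (1.0 - REL_IMPROVEMENT):
            best = loss
            since = 0
        else:
            since += 1
            if since >= cfg.plateau_patience:
                lr *= cfg.lr_decay_factor
                since = 0
    return lr, since


def adapt_lr(history: TrainHistory, cfg: TrainConfig) -> float:
    """Learning rate implied by the recorded train-loss trace."""
    if not history.train_loss:
        raise ValueError("at least one epoch must be recorded")
    return _plateau_replay(history.train_loss, cfg)[0]


def samples_to_arrays(samples: list[LabeledSample]):
    x = np.stack([s.image for s in samples])
    y = np.array([LABELS.index(s.label) for s in samples])
    return x, y


def _accuracy(model: AMSNet, x: np.ndarray, y: np.ndarray,
              batch_size: int = 16) -> float:
    correct = 0
    for i in range(0, len(x), batch_size):
        logits = model.predict_logits(x[i:i + batch_size])
        correct += int((logits.argmax(axis=1) == y[i:i + batch_size]).sum())
    return correct / len(x)


def fit_arrays(model: AMSNet, x_train: np.ndarray, y_train: np.ndarray,
               x_val: np.ndarray, y_val: np.ndarray,
               cfg: TrainConfig | None = None):
    """Core loop over raw arrays; returns (model, TrainHistory).

    The returned model carries the best-on-validation weights (including
    batch-norm running statistics captured at that epoch).
    """
    cfg = cfg or TrainConfig()
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    n_classes = model.cfg.num_classes
    if cfg.class_weights == "auto":
        weights = auto_class_weights(y_train, n_classes)
    else:
        weights = np.asarray(cfg.class_weights, dtype=np.float64)
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model, lr=cfg.initial_lr, betas=cfg.betas,
                weight_decay=cfg.weight_decay)
    history = TrainHistory()
    best_acc = -1.0
    best_state = None
    last_best_loss = np.inf
    stall = 0
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(len(x_train))
        loss_sum = 0.0
        wt_sum = 0.0
        for i in range(0, len(perm), cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            xb = model.prepare_input(x_train[idx])
            yb = y_train[idx]
            logits = model.forward(xb, training=True)
            loss, dlogits = weighted_cross_entropy(
                logits, yb, weights, return_grad=True)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            wb = weights[yb].sum()
            loss_sum += loss * wb
            wt_sum += wb
        epoch_loss = loss_sum / wt_sum
        history.train_loss.append(float(epoch_loss))
        val_acc = _accuracy(model, x_val, y_val)
        history.val_accuracy.append(float(val_acc))
        opt.lr, _ = _plateau_replay(history.train_loss, cfg)
        history.lr.append(float(opt.lr))
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = (copy.deepcopy(model.state_dict()),
                          copy.deepcopy(model.buffers_dict()))
        # stopping: no relative train-loss improvement for stop_patience
        if epoch_loss < last_best_loss * (1.0 - REL_IMPROVEMENT):
            last_best_loss = epoch_loss
            stall = 0
        else:
            stall += 1
        if epoch >= cfg.min_epochs and stall >= cfg.stop_patience:
            break
    model.load_state_dict(best_state[0])
    model.load_buffers_dict(best_state[1])
    return model, history


def train(model_cfg: ModelConfig, train_cfg: TrainConfig,
          split: DatasetSplit):
    """Train on a DatasetSplit; returns (model, TrainHistory)."""
    if not split.train or not split.validation:
        raise ValueError("train and validation splits must be non-empty")
    x_tr, y_tr = samples_to_arrays(split.train)
    x_va, y_va = samples_to_arrays(split.validation)
    model = AMSNet(model_cfg)
    return fit_arrays(model, x_tr, y_tr, x_va, y_va, train_cfg)
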